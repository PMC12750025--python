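"""Reduced massive-sampling scenarios: gating, trimming and cost accounting.

A scenario decides, per interface, whether massive sampling is worth running
at all (a median-ipTM *gate* on the default-run baseline) and, if so, how
much of the full plan to run (*intensity*: 67 -> 33 samples per NN model;
*diversity*: 8 -> 5 parameter sets).  Interfaces whose baseline median ipTM
is at or above the gate threshold fall back to the 25-model AF2 baseline —
they are never dropped outright, since every interface is still scored.

The eight presets:

========  =====  ===============  ==========
name      gate   samples/model    sets kept
========  =====  ===============  ==========
MF-best   none   67               all 8
S1        0.8    67               all 8
S2        0.65   67               all 8
S3        0.57   67               all 8
S4        none   33               5
S5        0.65   33               5
S6        0.57   33               5
AF2-baseline  — baseline pool only —
========  =====  ===============  ==========

Gate comparisons are strict: an interface is gated IN (massive sampling
runs) iff its baseline median ipTM is strictly below the threshold.
Intensity reduction keeps ``sample_index < samples_per_model`` within each
(parameter set, NN model) — a deterministic truncation emulating a smaller
run; a seeded random subsample is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingBaselineError
from .metrics import CAPRI_CLASSES, CLASS_RANK, effective_classes
from .store import KEY_COLUMNS, KEPT_SETS

SCENARIO_NAMES = ("MF-best", "S1", "S2", "S3", "S4", "S5", "S6", "AF2-baseline")


@dataclass(frozen=True)
class ScenarioSpec:
    """One sampling strategy: optional gate + trimming rules.

    ``gate_threshold`` is the median-ipTM cut (absent = no gating);
    ``parameter_sets_kept`` of ``None`` keeps every set in the pool;
    ``baseline_only`` marks the AF2-baseline reference strategy.  Gated-out
    interfaces fall back to the AF2-baseline pool.
    """

    name: str
    gate_threshold: float | None = None
    samples_per_model: int = 67
    parameter_sets_kept: tuple[str, ...] | None = None
    baseline_only: bool = False
    fallback: str = "af2_baseline"


def scenario_catalog() -> dict[str, ScenarioSpec]:
    """The eight preset strategies, keyed by name."""
    full, reduced = 67, 33
    return {
        "MF-best": ScenarioSpec("MF-best", None, full, None),
        "S1": ScenarioSpec("S1", 0.8, full, None),
        "S2": ScenarioSpec("S2", 0.65, full, None),
        "S3": ScenarioSpec("S3", 0.57, full, None),
        "S4": ScenarioSpec("S4", None, reduced, KEPT_SETS),
        "S5": ScenarioSpec("S5", 0.65, reduced, KEPT_SETS),
        "S6": ScenarioSpec("S6", 0.57, reduced, KEPT_SETS),
        "AF2-baseline": ScenarioSpec("AF2-baseline", None, full, None, baseline_only=True),
    }


def _gated_out(spec: ScenarioSpec, median_iptm: float) -> bool:
    # gated IN means "run massive sampling": median strictly below threshold
    return spec.gate_threshold is not None and median_iptm >= spec.gate_threshold


def apply_scenario(records: pd.DataFrame,
                   baseline_records: pd.DataFrame,
                   baselines: pd.DataFrame,
                   spec: ScenarioSpec,
                   interface_targets: Mapping[str, str],
                   gate_level: str = "interface",
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-interface record subset under one scenario.

    Parameters
    ----------
    records, baseline_records : DataFrame
        Clash-filtered pool and baseline record tables.
    baselines : DataFrame
        Baseline summaries indexed by interface with a ``median_iptm`` column.
    interface_targets : mapping
        interface -> target, covering every interface to report.
    gate_level : {"interface", "target"}
        ``"target"`` gates a whole target by the minimum of its interfaces'
        baseline medians.
    rng : numpy Generator, optional
        If given, intensity reduction draws a random subsample of sample
        indices per (parameter set, NN model) instead of truncating.

    Returns the selected records with two extra columns: ``interface`` and
    ``source`` (``"pool"`` or ``"baseline"``).
    """
    if gate_level not in ("interface", "target"):
        raise ConfigError(f"unknown gate_level {gate_level!r}")

    needs_gate = spec.gate_threshold is not None and not spec.baseline_only
    if needs_gate:
        missing = [i for i in interface_targets if i not in baselines.index]
        if missing:
            raise MissingBaselineError(
                f"no baseline summary for interface(s) {sorted(missing)} "
                f"under gated scenario {spec.name!r}")

    target_min: dict[str, float] = {}
    if needs_gate and gate_level == "target":
        med = baselines.loc[list(interface_targets), "median_iptm"]
        tgt = pd.Series({i: interface_targets[i] for i in interface_targets})
        target_min = med.groupby(tgt.reindex(med.index)).min().to_dict()

    pool_by_target = dict(tuple(records.groupby("target", sort=False)))
    base_by_target = dict(tuple(baseline_records.groupby("target", sort=False)))

    chunks = []
    for iface, target in interface_targets.items():
        if spec.baseline_only:
            use_baseline = True
        elif needs_gate:
            med = (target_min[target] if gate_level == "target"
                   else float(baselines.loc[iface, "median_iptm"]))
            use_baseline = _gated_out(spec, med)
        else:
            use_baseline = False

        if use_baseline:
            sub = base_by_target.get(target)
            if sub is None:
                raise MissingBaselineError(
                    f"no baseline records for target {target!r} (interface {iface!r})")
            sub = sub.copy()
            sub["source"] = "baseline"
        else:
            sub = pool_by_target.get(target)
            if sub is None:
                sub = records.iloc[0:0]
            mask = np.ones(len(sub), dtype=bool)
            if spec.parameter_sets_kept is not None:
                mask &= sub["parameter_set"].isin(spec.parameter_sets_kept).to_numpy()
            if rng is None:
                mask &= (sub["sample_index"] < spec.samples_per_model).to_numpy()
                sub = sub.loc[mask].copy()
            else:
                sub = sub.loc[mask]
                sub = _random_intensity(sub, spec.samples_per_model, rng)
            sub["source"] = "pool"
        sub["interface"] = iface
        chunks.append(sub)
    if not chunks:
        out = records.iloc[0:0].copy()
        out["source"] = pd.Series(dtype=str)
        out["interface"] = pd.Series(dtype=str)
        return out
    return pd.concat(chunks, ignore_index=True)


def _random_intensity(sub: pd.DataFrame, samples_per_model: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Seeded random subsample of sample indices within each (set, model)."""
    keep = []
    for _, grp in sub.groupby(["parameter_set", "nn_model"], sort=False):
        n = min(samples_per_model, len(grp))
        keep.append(grp.iloc[np.sort(rng.choice(len(grp), size=n, replace=False))])
    return pd.concat(keep).sort_index().copy()


def compute_cost(subsets: pd.DataFrame,
                 weights: Mapping[str, float] | None = None
                 ) -> tuple[float, pd.Series]:
    """Compute-cost accounting for a scenario's selected records.

    Each retained record costs the weight of its parameter set (default 1, so
    unit-weight cost equals subset cardinality); gated-out interfaces
    contribute their baseline-pool rows.  Returns ``(total, per_interface)``.
    """
    if subsets.empty:
        return 0.0, pd.Series(dtype=float, name="cost")
    if weights is None:
        w = pd.Series(1.0, index=subsets.index)
    else:
        present = subsets["parameter_set"].unique()
        unknown = [s for s in present if s not in weights]
        if unknown:
            raise ConfigError(f"no cost weight for parameter set(s) {sorted(unknown)}")
        w = subsets["parameter_set"].map(weights).astype(float)
    per_interface = w.groupby(subsets["interface"]).sum().rename("cost")
    return float(w.sum()), per_interface


def recycle_weights(plan) -> dict[str, float]:
    """Cost weights proportional to each set's recycle count (GPU-time proxy)."""
    return {ps.name: float(ps.recycles) for ps in plan.parameter_sets}


@dataclass(frozen=True)
class ScenarioResult:
    """Evaluation of one scenario: per-interface bests and pool-wide totals."""

    scenario: str
    per_interface: pd.DataFrame  # n_records, best_dockq, best_class, cost
    cumulative_dockq: float
    class_counts: Mapping[str, int]  # counts of per-interface best classes
    total_cost: float


def _best_per_interface(subset: pd.DataFrame, all_scores: pd.DataFrame) -> pd.DataFrame:
    """Best DockQ / best class per interface over a scenario subset."""
    merged = subset[KEY_COLUMNS + ["interface"]].merge(
        all_scores, on=KEY_COLUMNS + ["interface"], how="inner")
    merged = merged.assign(_rank=merged["_class"].map(CLASS_RANK))
    g = merged.groupby("interface", sort=False)
    out = g.agg(n_scored=("dockq", "size"), best_dockq=("dockq", "max"),
                _best_rank=("_rank", "max"))
    out["best_class"] = [CAPRI_CLASSES[r] for r in out["_best_rank"]]
    return out.drop(columns="_best_rank")


def scenario_report(records: pd.DataFrame, scores: pd.DataFrame,
                    baseline_records: pd.DataFrame, baseline_scores: pd.DataFrame,
                    baselines: pd.DataFrame,
                    specs: Iterable[ScenarioSpec] | None = None,
                    interface_targets: Mapping[str, str] | None = None,
                    gate_level: str = "interface",
                    weights: Mapping[str, float] | None = None
                    ) -> dict[str, ScenarioResult]:
    """Evaluate scenarios: per-interface best model and pool-wide totals.

    ``records``/``scores`` must be clash-filtered.  For each scenario the
    best DockQ and best CAPRI class per interface are taken over the
    scenario's subset; totals are the cumulative DockQ, the per-interface
    best-class counts and the total cost.
    """
    from .metrics import interface_target_map

    if specs is None:
        specs = scenario_catalog().values()
    if interface_targets is None:
        interface_targets = interface_target_map(scores)

    all_scores = pd.concat([scores, baseline_scores], ignore_index=True)
    all_scores = all_scores.assign(_class=effective_classes(all_scores))

    results: dict[str, ScenarioResult] = {}
    for spec in specs:
        subset = apply_scenario(records, baseline_records, baselines, spec,
                                interface_targets, gate_level=gate_level)
        per_iface = _best_per_interface(subset, all_scores)
        n_records = subset.groupby("interface", sort=False).size().rename("n_records")
        total_cost, per_cost = compute_cost(subset, weights)
        per_iface = per_iface.join(n_records).join(per_cost)
        counts = {c: int((per_iface["best_class"] == c).sum()) for c in CAPRI_CLASSES}
        results[spec.name] = ScenarioResult(
            scenario=spec.name,
            per_interface=per_iface,
            cumulative_dockq=float(per_iface["best_dockq"].sum()),
            class_counts=counts,
            total_cost=total_cost,
        )
    return results


def scenario_totals_frame(results: Mapping[str, ScenarioResult]) -> pd.DataFrame:
    """One-row-per-scenario summary table (cumulative DockQ, counts, cost)."""
    rows = []
    for name, res in results.items():
        row = {"scenario": name, "cumulative_dockq": res.cumulative_dockq,
               "total_cost": res.total_cost}
        for c in CAPRI_CLASSES:
            row[f"n_{c}"] = res.class_counts[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
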