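"""Synthetic prediction pools with known difficulty ground truth.

The generator emulates the *summary structure* of massive-sampling score
data — not real AlphaFold outputs.  Per interface it plants a best model
(``planted_max``) and draws a DockQ bulk whose shape encodes the intended
difficulty class:

* **easy** — a large near-max component (bulk within ``top_width`` of the
  planted maximum) over a lower tail, so the top-quartile spread stays small;
* **hard** — either an *outlier* interface (low bulk plus a handful of
  planted outliers lifting the maximum above 0.6 with a large spread) or a
  *mid* interface (bulk capped by a maximum between 0.4 and 0.6);
* **extreme** — the whole distribution capped below 0.4.

ipTM is a noisy affine transform of DockQ plus a class-level offset, giving
an informative but imperfect confidence ranking; pTM rides slightly above
ipTM.  A 25-model default-run baseline per interface draws its median ipTM
from a class-dependent interface-level distribution (easy centred at 0.80,
hard at 0.68, extreme at 0.48) so that median ipTM separates trivial from
non-trivial interfaces imperfectly, as a real triage score would.  Baseline
ipTM is deliberately uncoupled from baseline DockQ.

Two stylised facts of the study data are reproduced as switchable modifiers:
the 3-recycle parameter set is systematically weak (its DockQ scaled down,
and never hosting planted models), and one hard interface hides its outliers
in a single parameter set (the "T296.1" anecdote).

All randomness flows from a single seed through a hierarchical
``numpy.random.SeedSequence`` derivation (one child per interface), so any
interface's pool is reproducible independently and identical (config, seed)
pairs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .difficulty import EASY_DOCKQ_MIN, EASY_MAX_SPREAD, EXTREME_DOCKQ_MAX
from .errors import ConfigError
from .metrics import capri_class_array
from .store import (
    AF2_BASELINE_SET,
    KEY_COLUMNS,
    R3_SET,
    RECORD_COLUMNS,
    SCORE_COLUMNS,
    SamplingPlan,
    multimer_nn_models,
    standard_multimer_plan,
    write_prediction_table,
)

TRUTH_COLUMNS = ["interface", "target", "label", "subtype", "planted_max",
                 "planted_parameter_set", "planted_nn_model", "planted_sample_index",
                 "bulk_cap", "baseline_center"]


@dataclass(frozen=True)
class ClassProfile:
    """Effect sizes of one difficulty class.

    ``planted_max`` bounds the interface-level uniform draw of the best
    model's DockQ; ``iptm`` is the (intercept, slope, noise sd) of the
    DockQ -> ipTM transform; ``baseline_center`` the (mean, sd) of the
    interface-level baseline ipTM centre.  Fields used by one class only are
    ignored by the others.
    """

    planted_max: tuple[float, float]
    iptm: tuple[float, float, float]
    baseline_center: tuple[float, float]
    baseline_noise: float = 0.04
    # easy
    top_frac: float = 0.6
    top_width: float = 0.15
    tail_beta: tuple[float, float] = (2.0, 2.0)
    tail_cap_factor: float = 0.7
    baseline_top_frac: float = 0.7
    # hard
    outlier_frac: float = 0.6
    n_outliers: tuple[int, int] = (10, 40)
    outlier_width: float = 0.08
    bulk_beta: tuple[float, float] = (2.0, 4.0)
    bulk_cap: tuple[float, float] = (0.32, 0.45)
    mid_planted: tuple[float, float] = (0.44, 0.58)
    mid_bulk_beta: tuple[float, float] = (2.0, 3.0)


DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "easy": ClassProfile(
        planted_max=(0.68, 0.95),
        iptm=(0.35, 0.55, 0.05),
        baseline_center=(0.80, 0.11),
    ),
    "hard": ClassProfile(
        planted_max=(0.62, 0.88),
        iptm=(0.33, 0.60, 0.05),
        baseline_center=(0.68, 0.11),
    ),
    "extreme": ClassProfile(
        planted_max=(0.15, 0.38),
        bulk_beta=(1.5, 6.0),
        iptm=(0.20, 0.50, 0.04),
        baseline_center=(0.48, 0.10),
    ),
}


@dataclass
class GeneratorConfig:
    """Benchmark layout, effect sizes and contamination settings.

    Defaults mirror the study conditions: 41 easy / 17 hard / 7 extreme
    interfaces, the full 8-set x 15-model x 67-sample plan, a 25-model
    baseline per interface.
    """

    n_easy: int = 41
    n_hard: int = 17
    n_extreme: int = 7
    plan: SamplingPlan = field(default_factory=standard_multimer_plan)
    seed: int = 0
    baseline_n: int = 25
    clash_rate: float = 0.02
    weak_r3: bool = True
    r3_factor: float = 0.65
    t296_mode: bool = True
    t296_set: str = "afm_dropout_noSM_woTemplates"
    profiles: dict[str, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))

    def __post_init__(self) -> None:
        if min(self.n_easy, self.n_hard, self.n_extreme) < 0:
            raise ConfigError("interface counts must be >= 0")
        if not 0.0 <= self.clash_rate < 1.0:
            raise ConfigError("clash_rate must be in [0, 1)")
        if self.baseline_n <= 0:
            raise ConfigError("baseline_n must be positive")
        for label, prof in self.profiles.items():
            _validate_profile(label, prof)


def _validate_profile(label: str, prof: ClassProfile) -> None:
    lo, hi = prof.planted_max
    if not 0.0 < lo <= hi < 1.0:
        raise ConfigError(f"{label}: planted_max range {prof.planted_max} invalid")
    if label == "extreme" and hi >= EXTREME_DOCKQ_MAX:
        raise ConfigError(
            f"extreme: planted max {hi} must stay below {EXTREME_DOCKQ_MAX}")
    if label == "easy":
        if lo <= EASY_DOCKQ_MIN:
            raise ConfigError(f"easy: planted max must exceed {EASY_DOCKQ_MIN}")
        if prof.top_width > EASY_MAX_SPREAD:
            raise ConfigError(
                f"easy: top_width {prof.top_width} exceeds the "
                f"{EASY_MAX_SPREAD} spread budget")
        if prof.tail_cap_factor > 1.0 - prof.top_width / lo:
            raise ConfigError("easy: tail component may overlap the top component")
    if label == "hard":
        if lo <= EASY_DOCKQ_MIN or hi >= 1.0:
            raise ConfigError("hard: outlier planted max must lie in (0.6, 1)")
        mlo, mhi = prof.mid_planted
        if not EXTREME_DOCKQ_MAX < mlo <= mhi < EASY_DOCKQ_MIN:
            raise ConfigError("hard: mid planted max must lie in (0.4, 0.6)")
        if not 0 <= prof.n_outliers[0] <= prof.n_outliers[1]:
            raise ConfigError("hard: invalid n_outliers range")


# ---------------------------------------------------------------------------
# assignment of rows to (parameter set, NN model, sample index)
# ---------------------------------------------------------------------------

def _plan_assignment(plan: SamplingPlan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    roster = multimer_nn_models()
    sets, models, idx = [], [], []
    for ps in plan:
        names = (roster[:ps.n_nn_models] if ps.n_nn_models <= len(roster)
                 else [f"model_{m}" for m in range(1, ps.n_nn_models + 1)])
        sets.append(np.repeat(ps.name, ps.size))
        models.append(np.repeat(names, ps.samples_per_model))
        idx.append(np.tile(np.arange(ps.samples_per_model), ps.n_nn_models))
    return (np.concatenate(sets), np.concatenate(models),
            np.concatenate(idx).astype(int))


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# per-interface generation
# ---------------------------------------------------------------------------

def generate_interface_pool(label: str,
                            plan: SamplingPlan | None = None,
                            seed: int | None = None,
                            config: GeneratorConfig | None = None,
                            *,
                            target: str = "T001",
                            interface: str | None = None,
                            force_subtype: str | None = None,
                            outlier_home_set: str | None = None,
                            rng: np.random.Generator | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One interface's full pool: (records, interface scores, truth row).

    The truth row names the intended label, the planted best model and its
    DockQ, so downstream tests can score label and model recovery.
    """
    if config is None:
        config = GeneratorConfig()
    if label not in config.profiles:
        raise ConfigError(f"unknown difficulty label {label!r}")
    prof = config.profiles[label]
    _validate_profile(label, prof)
    plan = plan if plan is not None else config.plan
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if interface is None:
        interface = f"{target}.1"

    sets, models, idx = _plan_assignment(plan)
    n = len(sets)
    r3_rows = sets == R3_SET if config.weak_r3 else np.zeros(n, dtype=bool)

    # eligible rows for planted models: never the weak 3-recycle set
    if outlier_home_set is not None and (sets == outlier_home_set).any():
        eligible = sets == outlier_home_set
    else:
        eligible = ~r3_rows if (~r3_rows).any() else np.ones(n, dtype=bool)

    subtype = label
    bulk_cap = np.nan
    if label == "easy":
        planted = rng.uniform(*prof.planted_max)
        top = rng.random(n) < prof.top_frac
        dockq = np.empty(n)
        dockq[top] = planted - prof.top_width * rng.beta(2.0, 3.0, int(top.sum()))
        dockq[~top] = (prof.tail_cap_factor * planted
                       * rng.beta(*prof.tail_beta, int((~top).sum())))
    elif label == "hard":
        subtype = force_subtype or (
            "hard-outlier" if rng.random() < prof.outlier_frac else "hard-mid")
        if subtype == "hard-outlier":
            planted = rng.uniform(*prof.planted_max)
            bulk_cap = rng.uniform(*prof.bulk_cap)
            dockq = bulk_cap * rng.beta(*prof.bulk_beta, n)
        elif subtype == "hard-mid":
            planted = rng.uniform(*prof.mid_planted)
            dockq = planted * rng.beta(*prof.mid_bulk_beta, n)
        else:
            raise ConfigError(f"unknown hard subtype {subtype!r}")
    elif label == "extreme":
        planted = rng.uniform(*prof.planted_max)
        dockq = planted * rng.beta(*prof.bulk_beta, n)
    else:  # pragma: no cover - guarded above
        raise ConfigError(f"unknown difficulty label {label!r}")

    if config.weak_r3 and r3_rows.any():
        dockq[r3_rows] *= config.r3_factor

    if subtype == "hard-outlier":
        k = int(rng.integers(prof.n_outliers[0], prof.n_outliers[1] + 1))
        k = max(k, 1)
        out_rows = rng.choice(np.flatnonzero(eligible), size=k, replace=False)
        dockq[out_rows] = rng.uniform(planted - prof.outlier_width, planted, k)
        planted_row = int(out_rows[0])
    else:
        planted_row = int(rng.choice(np.flatnonzero(eligible)))
    dockq[planted_row] = planted
    dockq = _clip01(dockq)

    # clash contamination: half over-count, half CAPRI-flagged; never the
    # planted record, so the intended maximum survives filtering
    contaminated = rng.random(n) < config.clash_rate
    contaminated[planted_row] = False
    coin = rng.random(n) < 0.5
    n_clashes = np.where(contaminated & coin,
                         301 + rng.integers(0, 200, n), 0)
    clash_flag = contaminated & ~coin

    a, b, sd = prof.iptm
    iptm = _clip01(a + b * dockq + rng.normal(0.0, sd, n))
    ptm = _clip01(iptm + 0.06 + rng.normal(0.0, 0.03, n))

    records = pd.DataFrame({
        "target": target, "parameter_set": sets, "nn_model": models,
        "sample_index": idx, "iptm": iptm, "ptm": ptm,
        "mean_plddt": np.nan, "n_clashes": n_clashes,
        "capri_clash_flag": clash_flag,
    })[RECORD_COLUMNS]
    scores = records[KEY_COLUMNS].copy()
    scores["interface"] = interface
    scores["dockq"] = dockq
    scores["capri_class"] = capri_class_array(dockq)
    scores = scores[SCORE_COLUMNS]

    truth = {
        "interface": interface, "target": target, "label": label,
        "subtype": subtype, "planted_max": float(planted),
        "planted_parameter_set": sets[planted_row],
        "planted_nn_model": models[planted_row],
        "planted_sample_index": int(idx[planted_row]),
        "bulk_cap": float(bulk_cap), "baseline_center": np.nan,
    }
    return records, scores, truth


def generate_baseline(label: str,
                      seed: int | None = None,
                      config: GeneratorConfig | None = None,
                      *,
                      target: str = "T001",
                      interface: str | None = None,
                      planted_max: float | None = None,
                      subtype: str | None = None,
                      bulk_cap: float | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """A target's default-run baseline: 25 records + scores + ipTM centre.

    Baseline DockQ is drawn from the class's *bulk* distribution (for easy
    interfaces, the same top/tail mixture as the pool) and is always bounded
    by the pool's planted maximum, so oracle dominance holds by
    construction.  When the pool-level draws (``planted_max`` etc.) are not
    supplied, fresh ones are drawn from the profile.
    """
    if config is None:
        config = GeneratorConfig()
    prof = config.profiles[label]
    _validate_profile(label, prof)
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if interface is None:
        interface = f"{target}.1"
    n = config.baseline_n

    if planted_max is None:
        if label == "hard":
            subtype = subtype or (
                "hard-outlier" if rng.random() < prof.outlier_frac else "hard-mid")
            planted_max = (rng.uniform(*prof.planted_max)
                           if subtype == "hard-outlier"
                           else rng.uniform(*prof.mid_planted))
        else:
            subtype = subtype or label
            planted_max = rng.uniform(*prof.planted_max)
    if label == "hard" and subtype == "hard-outlier" and bulk_cap is None:
        bulk_cap = rng.uniform(*prof.bulk_cap)

    if label == "easy":
        top = rng.random(n) < prof.baseline_top_frac
        dockq = np.empty(n)
        dockq[top] = planted_max - prof.top_width * rng.beta(2.0, 3.0, int(top.sum()))
        dockq[~top] = (prof.tail_cap_factor * planted_max
                       * rng.beta(*prof.tail_beta, int((~top).sum())))
    elif label == "hard" and subtype == "hard-outlier":
        dockq = bulk_cap * rng.beta(*prof.bulk_beta, n)
    elif label == "hard":
        dockq = planted_max * rng.beta(*prof.mid_bulk_beta, n)
    else:
        dockq = planted_max * rng.beta(*prof.bulk_beta, n)
    dockq = _clip01(dockq)

    mu, tau = prof.baseline_center
    center = float(np.clip(rng.normal(mu, tau), 0.02, 0.98))
    iptm = _clip01(center + rng.normal(0.0, prof.baseline_noise, n))
    ptm = _clip01(iptm + 0.06 + rng.normal(0.0, 0.03, n))

    roster = multimer_nn_models()[10:15]  # the v3 models run by the default setup
    per_model = -(-n // 5)  # ceil division; 25 -> the canonical 5 x 5 grid
    models = np.repeat(roster, per_model)[:n]
    sample_idx = np.tile(np.arange(per_model), 5)[:n]
    records = pd.DataFrame({
        "target": target, "parameter_set": AF2_BASELINE_SET,
        "nn_model": models, "sample_index": sample_idx.astype(int),
        "iptm": iptm, "ptm": ptm, "mean_plddt": np.nan,
        "n_clashes": 0, "capri_clash_flag": False,
    })[RECORD_COLUMNS]

    scores = records[KEY_COLUMNS].copy()
    scores["interface"] = interface
    scores["dockq"] = dockq
    scores["capri_class"] = capri_class_array(dockq)
    return records, scores[SCORE_COLUMNS], center


# ---------------------------------------------------------------------------
# whole benchmarks
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """A generated dataset: pools, baselines and the ground-truth table."""

    records: pd.DataFrame
    scores: pd.DataFrame
    baseline_records: pd.DataFrame
    baseline_scores: pd.DataFrame
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        """Write per-target pool/baseline tables plus ``truth.csv``.

        The truth table is a leakage guard: analysis stages never read it.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for target, recs in self.records.groupby("target", sort=False):
            scs = self.scores.loc[self.scores["target"] == target]
            write_prediction_table(recs, scs, directory / f"pool_{target}.csv")
        for target, recs in self.baseline_records.groupby("target", sort=False):
            scs = self.baseline_scores.loc[self.baseline_scores["target"] == target]
            write_prediction_table(recs, scs, directory / f"baseline_{target}.csv")
        self.truth.to_csv(directory / "truth.csv", index=False)


def generate_benchmark(config: GeneratorConfig | None = None) -> Benchmark:
    """Generate a full difficulty-structured benchmark from a single seed."""
    if config is None:
        config = GeneratorConfig()
    labels = (["easy"] * config.n_easy + ["hard"] * config.n_hard
              + ["extreme"] * config.n_extreme)
    if not labels:
        raise ConfigError("benchmark needs at least one interface")
    children = np.random.SeedSequence(config.seed).spawn(len(labels))

    recs, scs, brecs, bscs, truths = [], [], [], [], []
    first_hard = True
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        target = f"T{i + 1:03d}"
        kwargs: dict = {}
        if label == "hard" and first_hard and config.t296_mode:
            kwargs = {"force_subtype": "hard-outlier",
                      "outlier_home_set": config.t296_set}
            first_hard = False
        r, s, truth = generate_interface_pool(
            label, config.plan, config=config, target=target, rng=rng, **kwargs)
        br, bs, center = generate_baseline(
            label, config=config, target=target,
            planted_max=truth["planted_max"], subtype=truth["subtype"],
            bulk_cap=(truth["bulk_cap"] if not np.isnan(truth["bulk_cap"]) else None),
            rng=rng)
        truth["baseline_center"] = center
        recs.append(r)
        scs.append(s)
        brecs.append(br)
        bscs.append(bs)
        truths.append(truth)

    return Benchmark(
        records=pd.concat(recs, ignore_index=True),
        scores=pd.concat(scs, ignore_index=True),
        baseline_records=pd.concat(brecs, ignore_index=True),
        baseline_scores=pd.concat(bscs, ignore_index=True),
        truth=pd.DataFrame(truths, columns=TRUTH_COLUMNS),
    )
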