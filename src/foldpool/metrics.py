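"""Per-interface distribution statistics and the DockQ -> CAPRI class mapping.

The difficulty analysis rests on two summary statistics of an interface's
DockQ distribution: the best model (``dockq_max``) and the spread of the top
of the distribution (``dockq_max - Q3``, the distance between the best model
and the third quartile).  A small spread means the pool is saturated with
models as good as the best one; a large spread means the best model is an
outlier that extra sampling had to dig up.

Quantiles use linear interpolation between order statistics (numpy's
``"linear"``, the classical type-7 rule); the convention is centralised in
:data:`QUANTILE_METHOD` because classification near spread = 0.2 can depend
on it.  Medians are the mean of the two central order statistics for even
counts (numpy's default), i.e. the 13th order statistic for the nominal
25-model baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyPoolError, TableValidationError

log = logging.getLogger(__name__)

#: CAPRI quality tiers, worst to best.
CAPRI_CLASSES = ("incorrect", "acceptable", "medium", "high")

#: Lower-inclusive DockQ boundaries of the positive classes.
CAPRI_BOUNDS = {"acceptable": 0.23, "medium": 0.49, "high": 0.80}

#: Quantile convention used everywhere (numpy method name; "linear" = type 7).
QUANTILE_METHOD = "linear"

CLASS_RANK = {c: i for i, c in enumerate(CAPRI_CLASSES)}


def capri_class(dockq: float) -> str:
    """Map a DockQ value to its CAPRI quality class (lower-inclusive bounds)."""
    if not 0.0 <= dockq <= 1.0:
        raise TableValidationError(f"dockq {dockq} outside [0, 1]")
    if dockq >= CAPRI_BOUNDS["high"]:
        return "high"
    if dockq >= CAPRI_BOUNDS["medium"]:
        return "medium"
    if dockq >= CAPRI_BOUNDS["acceptable"]:
        return "acceptable"
    return "incorrect"


def capri_class_array(dockq) -> np.ndarray:
    """Vectorised :func:`capri_class`."""
    d = np.asarray(dockq, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise TableValidationError("dockq outside [0, 1]")
    return np.select(
        [d >= CAPRI_BOUNDS["high"], d >= CAPRI_BOUNDS["medium"],
         d >= CAPRI_BOUNDS["acceptable"]],
        ["high", "medium", "acceptable"],
        default="incorrect",
    )


def third_quartile(values) -> float:
    """Q3 under the package-wide quantile convention."""
    return float(np.quantile(np.asarray(values, dtype=float), 0.75,
                             method=QUANTILE_METHOD))


def effective_classes(scores: pd.DataFrame) -> pd.Series:
    """CAPRI class per score row: assessor-provided wins, else derived from DockQ.

    Disagreements between provided and derived classes are counted and logged,
    never silently overwritten.
    """
    derived = pd.Series(capri_class_array(scores["dockq"].to_numpy()),
                        index=scores.index)
    if "capri_class" not in scores.columns:
        return derived
    provided = scores["capri_class"]
    have = provided.notna()
    if have.any():
        disagree = have & (provided != derived)
        if disagree.any():
            log.warning("provided CAPRI class disagrees with DockQ-derived class "
                        "for %d score(s); provided class wins", int(disagree.sum()))
    return provided.where(have, derived)


@dataclass(frozen=True)
class InterfaceSummary:
    """Distribution statistics of one interface's clash-filtered pool."""

    interface: str
    n_predictions: int
    dockq_max: float
    dockq_q3: float
    dockq_spread: float
    max_iptm: float
    class_counts: Mapping[str, int]


def summarize_interfaces(records: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-interface summary table from clash-filtered records and scores.

    Summaries must be computed after clash filtering; pass the retained
    records so only surviving scores are counted.  Returns one row per
    interface with columns ``target, n_predictions, dockq_max, dockq_q3,
    dockq_spread, max_iptm, n_high, n_medium, n_acceptable, n_incorrect``,
    indexed by interface.
    """
    if scores.empty:
        raise EmptyPoolError("no interface scores to summarize")
    from .store import KEY_COLUMNS  # local import to avoid cycle at module load

    kept = scores.merge(records[KEY_COLUMNS + ["iptm"]], on=KEY_COLUMNS, how="inner")
    if kept.empty:
        raise EmptyPoolError("no scores survive the record filter")
    kept = kept.assign(_class=effective_classes(kept))

    g = kept.groupby("interface", sort=False)
    out = g.agg(
        target=("target", "first"),
        n_predictions=("dockq", "size"),
        dockq_max=("dockq", "max"),
        dockq_q3=("dockq", third_quartile),
        max_iptm=("iptm", "max"),
    )
    out["dockq_spread"] = out["dockq_max"] - out["dockq_q3"]
    counts = (kept.groupby(["interface", "_class"], sort=False).size()
              .unstack(fill_value=0))
    for cls in CAPRI_CLASSES:
        out[f"n_{cls}"] = counts.get(cls, 0)
    return out


def interface_summary(scores: pd.DataFrame, records: pd.DataFrame) -> InterfaceSummary:
    """Summary of a single interface (scores restricted to one interface)."""
    if scores.empty:
        raise EmptyPoolError("empty score pool")
    ifaces = scores["interface"].unique()
    if len(ifaces) != 1:
        raise ValueError(f"expected scores for one interface, got {list(ifaces)}")
    row = summarize_interfaces(records, scores).iloc[0]
    return InterfaceSummary(
        interface=str(ifaces[0]),
        n_predictions=int(row["n_predictions"]),
        dockq_max=float(row["dockq_max"]),
        dockq_q3=float(row["dockq_q3"]),
        dockq_spread=float(row["dockq_spread"]),
        max_iptm=float(row["max_iptm"]),
        class_counts={c: int(row[f"n_{c}"]) for c in CAPRI_CLASSES},
    )


@dataclass(frozen=True)
class BaselineSummary:
    """Median baseline ipTM of one interface (the a-priori triage score)."""

    interface: str
    median_iptm: float
    n_baseline: int


def baseline_median_iptm(baseline_records: pd.DataFrame,
                         interface: str | None = None) -> BaselineSummary:
    """Median ipTM over one target's default-run (baseline) predictions."""
    if baseline_records.empty:
        raise EmptyPoolError(f"empty baseline pool for interface {interface!r}")
    med = float(np.median(baseline_records["iptm"].to_numpy(dtype=float)))
    name = interface if interface is not None else str(baseline_records["target"].iloc[0])
    return BaselineSummary(name, med, len(baseline_records))


def interface_target_map(scores: pd.DataFrame) -> dict[str, str]:
    """interface -> target mapping derived from a score table."""
    pairs = scores[["interface", "target"]].drop_duplicates()
    dup = pairs["interface"].duplicated()
    if dup.any():
        bad = pairs.loc[dup, "interface"].iloc[0]
        raise ValueError(f"interface {bad!r} maps to multiple targets")
    return dict(zip(pairs["interface"], pairs["target"]))


def baseline_summaries(baseline_records: pd.DataFrame,
                       interface_targets: Mapping[str, str]) -> pd.DataFrame:
    """Per-interface baseline summary table (``median_iptm``, ``n_baseline``).

    The median is computed per target over that target's baseline records and
    assigned to each of its interfaces.
    """
    if baseline_records.empty:
        raise EmptyPoolError("empty baseline pool")
    per_target = baseline_records.groupby("target")["iptm"].agg(["median", "size"])
    rows = []
    for iface, target in interface_targets.items():
        if target not in per_target.index:
            raise EmptyPoolError(f"no baseline records for target {target!r} "
                                 f"(interface {iface!r})")
        rows.append((iface, target, float(per_target.loc[target, "median"]),
                     int(per_target.loc[target, "size"])))
    out = pd.DataFrame(rows, columns=["interface", "target", "median_iptm", "n_baseline"])
    return out.set_index("interface")
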