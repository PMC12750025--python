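"""Data model and I/O for massive-sampling prediction pools.

A *pool* is the set of structure predictions produced for one target by a
sampling plan: an ordered collection of parameter sets, each running a number
of neural-network models for a number of samples per model.  Records carry
AlphaFold-style confidence scores (ipTM, pTM for multimers; mean pLDDT for
monomers) and clash information; interface scores attach a DockQ value (and
optionally a CAPRI class) to a record at one assessed interface.

In memory, pools are plain :class:`pandas.DataFrame` objects with the column
sets :data:`RECORD_COLUMNS` and :data:`SCORE_COLUMNS`; the dataclasses in this
module describe plans and parameter sets.  On disk, a pool is one wide
delimited-text table per target: record columns plus ``dockq:<interface>`` /
``capri:<interface>`` columns, one pair per assessed interface.

Row order in input tables is preserved and defines the stable tie-break order
used by all downstream selections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FormatError,
    MissingScoreError,
    SchemaError,
    TableValidationError,
)

log = logging.getLogger(__name__)

ENGINES = ("AFmassive", "ColabFold")

#: Columns that uniquely key one prediction.
KEY_COLUMNS = ["target", "parameter_set", "nn_model", "sample_index"]
#: Full per-prediction record schema.
RECORD_COLUMNS = KEY_COLUMNS + ["iptm", "ptm", "mean_plddt", "n_clashes", "capri_clash_flag"]
#: Long-form per-(prediction, interface) score schema.
SCORE_COLUMNS = KEY_COLUMNS + ["interface", "dockq", "capri_class"]

DOCKQ_PREFIX = "dockq:"
CAPRI_PREFIX = "capri:"

#: Default clash-count cutoff: predictions with more clashes are excluded.
MAX_CLASHES = 300

#: Name of the pseudo parameter set holding the default-run baseline.
AF2_BASELINE_SET = "af2_baseline"


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """One sampling configuration (dropout/templates/recycles/engine)."""

    name: str
    engine: str = "AFmassive"
    dropout_evoformer: bool = False
    dropout_structure_module: bool = False
    templates: bool = False
    recycles: int = 21
    n_nn_models: int = 15
    samples_per_model: int = 67

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ConfigError(f"unknown engine {self.engine!r}; expected one of {ENGINES}")
        if self.recycles < 0:
            raise ConfigError("recycles must be >= 0")
        if self.n_nn_models <= 0 or self.samples_per_model <= 0:
            raise ConfigError("n_nn_models and samples_per_model must be positive")

    @property
    def size(self) -> int:
        return self.n_nn_models * self.samples_per_model


@dataclass(frozen=True)
class SamplingPlan:
    """An ordered collection of parameter sets defining a pool."""

    name: str
    parameter_sets: tuple[ParameterSet, ...]

    def __post_init__(self) -> None:
        names = [ps.name for ps in self.parameter_sets]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate parameter-set names in plan {self.name!r}")

    def __iter__(self):
        return iter(self.parameter_sets)

    @property
    def size(self) -> int:
        return plan_size(self)

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(ps.name for ps in self.parameter_sets)


def plan_size(plan: SamplingPlan) -> int:
    """Total number of predictions the plan produces (sum of set sizes)."""
    if not plan.parameter_sets:
        raise ConfigError(f"plan {plan.name!r} is empty")
    return sum(ps.size for ps in plan.parameter_sets)


# The eight production parameter sets: six AFmassive + two ColabFold.
# Fields: (name, engine, dropout_evoformer, dropout_structure_module,
#          templates, recycles)
_STANDARD_SETS = (
    ("afm_basic", "AFmassive", False, False, True, 21),
    ("afm_woTemplates", "AFmassive", False, False, False, 21),
    ("afm_dropout_full", "AFmassive", True, True, True, 21),
    ("afm_dropout_full_woTemplates", "AFmassive", True, True, False, 21),
    ("afm_dropout_full_woTemplates_r3", "AFmassive", True, True, False, 3),
    ("afm_dropout_noSM_woTemplates", "AFmassive", True, False, False, 21),
    ("cf_woTemplates", "ColabFold", False, False, False, 21),
    ("cf_dropout_full_woTemplates", "ColabFold", True, True, False, 21),
)

#: The three sets dropped when trimming sampling diversity from 8 to 5.
REMOVED_SETS = (
    "afm_dropout_full_woTemplates_r3",
    "cf_dropout_full_woTemplates",
    "afm_dropout_full_woTemplates",
)

#: The five sets retained by the reduced-diversity plans (S4-S6).
KEPT_SETS = tuple(
    row[0] for row in _STANDARD_SETS if row[0] not in REMOVED_SETS
)

#: The only parameter set run with 3 recycles (systematically weak).
R3_SET = "afm_dropout_full_woTemplates_r3"


def _build_sets(n_nn_models: int, samples_per_model: int,
                names: Iterable[str] | None = None) -> tuple[ParameterSet, ...]:
    keep = None if names is None else set(names)
    out = []
    for name, engine, d_evo, d_sm, tmpl, rec in _STANDARD_SETS:
        if keep is not None and name not in keep:
            continue
        out.append(ParameterSet(name, engine, d_evo, d_sm, tmpl, rec,
                                n_nn_models, samples_per_model))
    return tuple(out)


def standard_multimer_plan(samples_per_model: int = 67) -> SamplingPlan:
    """The full production plan: 8 sets x 15 NN models x 67 samples = 8040."""
    return SamplingPlan("standard_multimer", _build_sets(15, samples_per_model))


def reduced_multimer_plan(samples_per_model: int = 33) -> SamplingPlan:
    """The trimmed plan: 5 retained sets x 15 models x 33 samples = 2475."""
    return SamplingPlan("reduced_multimer", _build_sets(15, samples_per_model, KEPT_SETS))


def monomer_plan(samples_per_model: int = 201) -> SamplingPlan:
    """Monomer plan: only 5 NN models exist, so 201 samples/model keeps 1005 per set."""
    return SamplingPlan("standard_monomer", _build_sets(5, samples_per_model))


def af2_baseline_plan() -> SamplingPlan:
    """The no-massive-sampling reference: one default run, 5 models x 5 samples = 25."""
    ps = ParameterSet(AF2_BASELINE_SET, engine="AFmassive", templates=True,
                      recycles=3, n_nn_models=5, samples_per_model=5)
    return SamplingPlan(AF2_BASELINE_SET, (ps,))


def multimer_nn_models() -> list[str]:
    """The 15 multimer network identifiers: 3 versions x 5 base models."""
    return [f"multimer_v{v}_model_{m}" for v in (1, 2, 3) for m in range(1, 6)]


def monomer_nn_models() -> list[str]:
    """The 5 monomer network identifiers (a single released version)."""
    return [f"model_{m}" for m in range(1, 6)]


def plan_to_yaml(plan: SamplingPlan, path: str | Path) -> None:
    doc = {
        "name": plan.name,
        "parameter_sets": [
            {
                "name": ps.name,
                "engine": ps.engine,
                "dropout_evoformer": ps.dropout_evoformer,
                "dropout_structure_module": ps.dropout_structure_module,
                "templates": ps.templates,
                "recycles": ps.recycles,
                "n_nn_models": ps.n_nn_models,
                "samples_per_model": ps.samples_per_model,
            }
            for ps in plan.parameter_sets
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def plan_from_yaml(path: str | Path) -> SamplingPlan:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        sets = tuple(ParameterSet(**entry) for entry in doc["parameter_sets"])
        return SamplingPlan(doc["name"], sets)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed plan file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# ranking confidence
# ---------------------------------------------------------------------------

def ranking_confidence(iptm: float | None = None, ptm: float | None = None,
                       mean_plddt: float | None = None) -> float:
    """AlphaFold's model-selection score.

    Multimers: ``0.8 * ipTM + 0.2 * pTM`` in [0, 1].  Monomers: the mean
    pLDDT in [0, 100].  Higher always means more confident.
    """
    def _ok(x):
        return x is not None and not (isinstance(x, float) and np.isnan(x))

    if _ok(iptm) and _ok(ptm):
        return 0.8 * float(iptm) + 0.2 * float(ptm)
    if _ok(mean_plddt):
        return float(mean_plddt)
    raise MissingScoreError("record has neither (iptm, ptm) nor mean_plddt")


def ranking_confidence_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorised ranking confidence for a record table (one value per row)."""
    iptm = records["iptm"] if "iptm" in records else pd.Series(np.nan, index=records.index)
    ptm = records["ptm"] if "ptm" in records else pd.Series(np.nan, index=records.index)
    plddt = (records["mean_plddt"] if "mean_plddt" in records
             else pd.Series(np.nan, index=records.index))
    multimer = iptm.notna() & ptm.notna()
    monomer = plddt.notna()
    bad = ~(multimer | monomer)
    if bad.any():
        raise MissingScoreError(
            f"{int(bad.sum())} record(s) have neither (iptm, ptm) nor mean_plddt"
        )
    conf = np.where(multimer, 0.8 * iptm.to_numpy(float) + 0.2 * ptm.to_numpy(float),
                    plddt.to_numpy(float))
    return pd.Series(conf, index=records.index, name="ranking_confidence")


# ---------------------------------------------------------------------------
# clash filtering
# ---------------------------------------------------------------------------

def filter_clashes(records: pd.DataFrame, max_clashes: int = MAX_CLASHES
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop clash-contaminated predictions.

    A record is retained iff ``n_clashes <= max_clashes`` and its CAPRI clash
    flag is unset.  Returns ``(retained, exclusions)``; the exclusion report
    carries one row per removed record with a single ``reason`` (clash-count
    violations take precedence over the CAPRI flag, so reasons partition the
    removed set).  Missing ``n_clashes`` is treated as 0 with a warning —
    exclusion is opt-in on evidence.
    """
    records = records.copy()
    if "n_clashes" not in records.columns:
        log.warning("n_clashes column absent; treating all clash counts as 0")
        records["n_clashes"] = 0
    elif records["n_clashes"].isna().any():
        n = int(records["n_clashes"].isna().sum())
        log.warning("n_clashes missing for %d record(s); treated as 0", n)
        records["n_clashes"] = records["n_clashes"].fillna(0)
    records["n_clashes"] = records["n_clashes"].astype(int)
    if "capri_clash_flag" not in records.columns:
        records["capri_clash_flag"] = False
    flag = records["capri_clash_flag"].fillna(False).astype(bool)

    over = records["n_clashes"].to_numpy() > max_clashes
    excluded = over | flag.to_numpy()
    retained = records.loc[~excluded].copy()
    report = records.loc[excluded].copy()
    report["reason"] = np.where(over[excluded], f"n_clashes>{max_clashes}", "capri_clash")
    return retained, report


# ---------------------------------------------------------------------------
# delimited-text tables
# ---------------------------------------------------------------------------

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "": False}


def _parse_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    out = series.fillna(False).astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise TableValidationError(f"cannot parse boolean value {bad!r}")
    return out.astype(bool)


def _check_unit_interval(df: pd.DataFrame, column: str) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    raw_bad = df[column].notna() & vals.isna()
    if raw_bad.any():
        row = int(np.flatnonzero(raw_bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise TableValidationError(f"non-numeric {column} at row {row}")
    out = vals.notna() & ((vals < 0.0) | (vals > 1.0))
    if out.any():
        row = int(np.flatnonzero(out.to_numpy())[0]) + 2
        raise TableValidationError(f"{column} out of [0,1] at row {row}")


def _detect_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_prediction_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one wide pool table into (records, interface scores).

    The table must name the key columns ``target, parameter_set, nn_model,
    sample_index``; confidence/clash columns are optional (monomer tables
    have no ipTM).  Every ``dockq:<interface>`` column yields one score row
    per record with a non-missing DockQ; a matching ``capri:<interface>``
    column supplies assessor-provided classes.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {', '.join(missing)}")

    for col in ("iptm", "ptm", "mean_plddt", "n_clashes"):
        if col not in df.columns:
            df[col] = np.nan
    for col in ("iptm", "ptm"):
        _check_unit_interval(df, col)
    if "capri_clash_flag" in df.columns:
        df["capri_clash_flag"] = _parse_bool(df["capri_clash_flag"])
    else:
        df["capri_clash_flag"] = False
    if df["n_clashes"].isna().all():
        log.warning("%s: no n_clashes column; clash counts default to 0", path.name)
    df["n_clashes"] = df["n_clashes"].fillna(0).astype(int)
    df["sample_index"] = df["sample_index"].astype(int)

    records = df[RECORD_COLUMNS].copy()

    ifaces = [c[len(DOCKQ_PREFIX):] for c in df.columns if c.startswith(DOCKQ_PREFIX)]
    blocks = []
    for iface in ifaces:
        dq_col = DOCKQ_PREFIX + iface
        _check_unit_interval(df, dq_col)
        block = df[KEY_COLUMNS].copy()
        block["interface"] = iface
        block["dockq"] = pd.to_numeric(df[dq_col])
        cap_col = CAPRI_PREFIX + iface
        block["capri_class"] = df[cap_col] if cap_col in df.columns else pd.NA
        blocks.append(block.loc[block["dockq"].notna()])
    if blocks:
        scores = pd.concat(blocks, ignore_index=True)[SCORE_COLUMNS]
    else:
        scores = pd.DataFrame(columns=SCORE_COLUMNS)
    return records, scores


def write_prediction_table(records: pd.DataFrame, scores: pd.DataFrame,
                           path: str | Path, sep: str = ",") -> None:
    """Write (records, scores) back to the wide single-table dialect."""
    wide = records[RECORD_COLUMNS].copy()
    for iface, block in scores.groupby("interface", sort=True):
        block = block.set_index(pd.MultiIndex.from_frame(block[KEY_COLUMNS]))
        idx = pd.MultiIndex.from_frame(wide[KEY_COLUMNS])
        wide[DOCKQ_PREFIX + str(iface)] = block["dockq"].reindex(idx).to_numpy()
        if block["capri_class"].notna().any():
            wide[CAPRI_PREFIX + str(iface)] = block["capri_class"].reindex(idx).to_numpy()
    wide.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# AlphaFold ranking-score JSON
# ---------------------------------------------------------------------------

_MULTIMER_KEY = "iptm+ptm"
_MONOMER_KEY = "plddts"


def read_af_ranking_scores(path: str | Path) -> tuple[dict[str, float], str]:
    """Read an AlphaFold ``ranking_debug``-style score file.

    Returns a model-name -> score mapping (in the file's ``order``) and the
    detected dialect, ``"multimer"`` or ``"monomer"``.  Files carrying both or
    neither score key are rejected rather than guessed.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    has_multi = _MULTIMER_KEY in data
    has_mono = _MONOMER_KEY in data
    if has_multi == has_mono:
        raise FormatError(
            f"{path.name}: expected exactly one of {_MULTIMER_KEY!r}/{_MONOMER_KEY!r}"
        )
    key, dialect = ((_MULTIMER_KEY, "multimer") if has_multi else (_MONOMER_KEY, "monomer"))
    score_map = data[key]
    order = data.get("order")
    if order is None:
        raise FormatError(f"{path.name}: missing 'order' list")
    missing = [m for m in order if m not in score_map]
    if missing:
        raise FormatError(f"{path.name}: order names models absent from score map: {missing}")
    return {m: float(score_map[m]) for m in order}, dialect


def write_af_ranking_scores(scores: Mapping[str, float], dialect: str,
                            path: str | Path) -> None:
    key = {"multimer": _MULTIMER_KEY, "monomer": _MONOMER_KEY}.get(dialect)
    if key is None:
        raise ConfigError(f"unknown dialect {dialect!r}")
    doc = {key: dict(scores), "order": list(scores)}
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# benchmark directories
# ---------------------------------------------------------------------------

def read_benchmark_dir(directory: str | Path
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read every ``pool_*`` / ``baseline_*`` table under a directory.

    Returns concatenated (records, scores, baseline_records, baseline_scores);
    file name order (sorted) fixes the cross-target row order.
    """
    directory = Path(directory)
    def _read_all(pattern):
        recs, scs = [], []
        for f in sorted(directory.glob(pattern)):
            r, s = read_prediction_table(f)
            recs.append(r)
            scs.append(s)
        if not recs:
            return (pd.DataFrame(columns=RECORD_COLUMNS),
                    pd.DataFrame(columns=SCORE_COLUMNS))
        return (pd.concat(recs, ignore_index=True),
                pd.concat(scs, ignore_index=True))

    records, scores = _read_all("pool_*.csv")
    brecords, bscores = _read_all("baseline_*.csv")
    return records, scores, brecords, bscores
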