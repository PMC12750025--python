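"""Interface difficulty: post-hoc classification and a-priori triage.

Difficulty is defined on the full massive-sampling DockQ distribution of an
interface:

* **extreme** — ``dockq_max < 0.4``: even massive sampling rarely yields an
  acceptable model;
* **easy** — ``dockq_max > 0.6`` and ``dockq_max - Q3 <= 0.2``: a routine run
  already saturates near the best model;
* **hard** — everything else: the mid-range maxima and the interfaces whose
  best model is an outlier of the distribution (large spread).  Massive
  sampling pays off most here.

The printed clauses leave the boundary values 0.4, 0.6 and spread = 0.2
ambiguous or doubly matched; the classifier evaluates extreme -> easy -> hard
with *hard* as the residual class, so ``dockq_max`` of exactly 0.4 or 0.6 is
hard, a perfect maximum with small spread is easy, and a spread of exactly
0.2 (with ``dockq_max > 0.6``) is easy.

Because difficulty can only be measured after the full pool exists, a
*triage* predictor estimates it a priori from the default-run (AF2-baseline)
median ipTM: hard and extreme interfaces form the positive "non-trivial"
class, and a LOW median ipTM predicts non-trivial.  ROC/AUC and an
F1-optimal threshold are provided; the shipped gate presets are 0.8 (S1,
permissive), 0.65 (S2, separates the easy/hard cores) and 0.57 (S3,
F1-optimal on the study data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import UndefinedAUCError

DIFFICULTY_LABELS = ("easy", "hard", "extreme")

#: dockq_max below which an interface is extreme.
EXTREME_DOCKQ_MAX = 0.4
#: dockq_max above which (with small spread) an interface is easy.
EASY_DOCKQ_MIN = 0.6
#: Largest top-distribution spread an easy interface may have.
EASY_MAX_SPREAD = 0.2

#: Named median-ipTM gate thresholds for the sampling scenarios.
TRIAGE_PRESETS = {"S1": 0.8, "S2": 0.65, "S3": 0.57}

#: Pool max-ipTM below which an interface is flagged as likely extreme.
POSTHOC_MAX_IPTM = 0.72

_RULE_EXTREME = f"dockq_max < {EXTREME_DOCKQ_MAX}"
_RULE_EASY = f"dockq_max > {EASY_DOCKQ_MIN} and dockq_spread <= {EASY_MAX_SPREAD}"
_RULE_HARD = "residual (neither extreme nor easy clause matched)"


@dataclass(frozen=True)
class DifficultyLabel:
    interface: str
    label: str
    rule_fired: str


def classify_difficulty(dockq_max: float, dockq_spread: float,
                        interface: str = "") -> DifficultyLabel:
    """Assign easy/hard/extreme from (dockq_max, dockq_max - Q3).

    Total and deterministic; precedence extreme -> easy -> hard (residual).
    """
    if dockq_max < EXTREME_DOCKQ_MAX:
        return DifficultyLabel(interface, "extreme", _RULE_EXTREME)
    if dockq_max > EASY_DOCKQ_MIN and dockq_spread <= EASY_MAX_SPREAD:
        return DifficultyLabel(interface, "easy", _RULE_EASY)
    return DifficultyLabel(interface, "hard", _RULE_HARD)


def assign_difficulty(summaries: pd.DataFrame) -> pd.DataFrame:
    """Add ``label`` and ``rule_fired`` columns to an interface-summary table."""
    dmax = summaries["dockq_max"].to_numpy(dtype=float)
    spread = summaries["dockq_spread"].to_numpy(dtype=float)
    extreme = dmax < EXTREME_DOCKQ_MAX
    easy = ~extreme & (dmax > EASY_DOCKQ_MIN) & (spread <= EASY_MAX_SPREAD)
    out = summaries.copy()
    out["label"] = np.select([extreme, easy], ["extreme", "easy"], default="hard")
    out["rule_fired"] = np.select([extreme, easy], [_RULE_EXTREME, _RULE_EASY],
                                  default=_RULE_HARD)
    return out


def nontrivial_truth(label: str | DifficultyLabel) -> bool:
    """True iff the label belongs to the non-trivial group (hard or extreme)."""
    if isinstance(label, DifficultyLabel):
        label = label.label
    if label not in DIFFICULTY_LABELS:
        raise ValueError(f"unknown difficulty label {label!r}")
    return label in ("hard", "extreme")


def nontrivial_mask(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    unknown = ~np.isin(arr, DIFFICULTY_LABELS)
    if unknown.any():
        raise ValueError(f"unknown difficulty label {arr[unknown][0]!r}")
    return np.isin(arr, ("hard", "extreme"))


def posthoc_extreme_flag(max_iptm: float) -> bool:
    """Post-hoc extreme indicator: pool max ipTM strictly below 0.72."""
    return max_iptm < POSTHOC_MAX_IPTM


# ---------------------------------------------------------------------------
# ROC / F1 machinery (direction fixed once: LOW score predicts positive)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """ROC curve for the rule "predict positive when score < threshold"."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    positive_class: str = "non-trivial"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def roc_points(scores, truth) -> RocCurve:
    """ROC curve and AUC for a score where LOW values predict the positive class.

    The curve is swept over all distinct score thresholds (no point
    dropping), starts at (0, 0) and ends at (1, 1); the trapezoidal AUC
    equals the pairwise-comparison probability with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be 1-d and the same length")
    if t.all() or not t.any():
        raise UndefinedAUCError("truth vector contains a single class; AUC undefined")
    fpr, tpr, thr = _skm.roc_curve(t, -s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=-thr, auc=auc)


def f1_optimal_threshold(scores, truth) -> tuple[float, float]:
    """Threshold maximizing F1 for "predict positive when score < threshold".

    Candidates are the midpoints between consecutive distinct sorted scores
    plus one value below the minimum and one above the maximum (the
    all-negative and all-positive rules); ties break toward the smaller
    threshold.  Returns ``(threshold, f1)``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if t.all() or not t.any():
        raise UndefinedAUCError("truth vector contains a single class")
    distinct = np.unique(s)
    if len(distinct) > 1:
        lo = distinct[0] - 0.5 * (distinct[1] - distinct[0])
        hi = distinct[-1] + 0.5 * (distinct[-1] - distinct[-2])
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        candidates = np.concatenate([[lo], mids, [hi]])
    else:
        candidates = np.array([distinct[0] - 0.5, distinct[0] + 0.5])

    pred = s[None, :] < candidates[:, None]
    tp = (pred & t).sum(axis=1)
    fp = (pred & ~t).sum(axis=1)
    fn = ((~pred) & t).sum(axis=1)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = int(np.argmax(f1))  # first maximum = smallest threshold
    return float(candidates[best]), float(f1[best])


# ---------------------------------------------------------------------------
# model/results interface for the triage fit
# ---------------------------------------------------------------------------

class InterfaceTriage:
    """Binary triage of interfaces from a per-interface confidence score.

    The model is the decision rule "flag the interface as non-trivial (run
    massive sampling) when its score falls below a threshold".  ``fit``
    sweeps the ROC curve, computes the AUC and selects the F1-optimal
    threshold.  Any per-interface score vector can be supplied; the study's
    named predictor is the AF2-baseline median ipTM.

    Parameters
    ----------
    scores : array-like
        One confidence score per interface; LOW predicts non-trivial.
    truth : array-like of bool
        Ground-truth non-trivial flags (hard or extreme).
    score_name : str
        Name of the predictor, used in the summary.
    """

    def __init__(self, scores, truth, score_name: str = "baseline median ipTM"):
        self.scores = np.asarray(scores, dtype=float)
        self.truth = np.asarray(truth, dtype=bool)
        self.score_name = score_name
        if self.scores.shape != self.truth.shape:
            raise ValueError("scores and truth must have the same length")

    @classmethod
    def from_summaries(cls, baseline: pd.DataFrame, labelled: pd.DataFrame,
                       score_column: str = "median_iptm") -> "InterfaceTriage":
        """Build from a baseline-summary table and a labelled-summary table.

        Both tables must be indexed by interface; ``labelled`` carries the
        ``label`` column produced by :func:`assign_difficulty`.
        """
        joined = baseline[[score_column]].join(labelled["label"], how="inner")
        if len(joined) < len(labelled):
            missing = set(labelled.index) - set(joined.index)
            raise ValueError(f"no baseline score for interface(s) {sorted(missing)}")
        return cls(joined[score_column].to_numpy(),
                   nontrivial_mask(joined["label"]),
                   score_name=score_column)

    def fit(self) -> "TriageResult":
        roc = roc_points(self.scores, self.truth)
        thr, f1 = f1_optimal_threshold(self.scores, self.truth)
        return TriageResult(model=self, roc=roc, auc=roc.auc,
                            threshold=thr, f1=f1,
                            n_pos=int(self.truth.sum()),
                            n_neg=int((~self.truth).sum()))


@dataclass(frozen=True)
class TriageResult:
    """Fitted triage: ROC curve, AUC and the F1-optimal gate threshold."""

    model: InterfaceTriage
    roc: RocCurve
    auc: float
    threshold: float
    f1: float
    n_pos: int
    n_neg: int

    def predict(self, scores, threshold: float | None = None) -> np.ndarray:
        """Non-trivial flags for new scores (score < threshold)."""
        thr = self.threshold if threshold is None else threshold
        return np.asarray(scores, dtype=float) < thr

    def summary(self) -> str:
        lines = [
            "Interface triage (predict non-trivial when score < threshold)",
            "=" * 62,
            f"predictor:            {self.model.score_name}",
            f"interfaces:           {self.n_pos + self.n_neg} "
            f"({self.n_pos} non-trivial, {self.n_neg} trivial)",
            f"AUC:                  {self.auc:.3f}",
            f"F1-optimal threshold: {self.threshold:.3f}",
            f"F1 at threshold:      {self.f1:.3f}",
            "preset gates:         "
            + ", ".join(f"{k}={v}" for k, v in TRIAGE_PRESETS.items()),
        ]
        return "\n".join(lines)
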