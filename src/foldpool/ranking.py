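"""Top-k model selection and CAPRI-style group ranking.

Selection mirrors CASP submission mechanics: a group picks its five
highest-confidence models *per target* (AlphaFold ranking confidence, stable
input order breaking ties), and the CAPRI assessors evaluate those same five
models *per interface* of the target.  A group's standing is then the pair

* weighted CAPRI score ``3 x high + 2 x medium + 1 x acceptable`` over its
  per-interface best classes ("incorrect" contributes 0 and is reported
  separately), and
* cumulative DockQ, the sum over interfaces of the best submitted model's
  DockQ (the DockQ maximum by default; a class-best variant — DockQ of the
  best model *by class* — is also computed).

Groups are ordered by weighted score, then cumulative DockQ, then group
identifier.

Reference pseudo-groups put a pool in context: ``MassiveFold-best`` (oracle
pick from the whole pool), ``AF2-baseline-best`` (oracle pick within the
25-model default run), ``AF2-baseline`` (the default run's max-ipTM model,
i.e. what a routine user submits) and ``top-confidence`` (the five
highest-confidence models of the whole pool, the massive-sampling baseline
submission).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPoolError, MissingScoreError
from .metrics import CAPRI_CLASSES, CLASS_RANK, effective_classes
from .store import KEY_COLUMNS, ranking_confidence_frame

#: Weights of the per-interface best classes in the ranking statistic.
CLASS_WEIGHTS = {"high": 3, "medium": 2, "acceptable": 1, "incorrect": 0}


@dataclass(frozen=True)
class Submission:
    """One group's ordered model picks for one target (at most k models)."""

    group: str
    target: str
    models: pd.DataFrame  # selected records, descending confidence


@dataclass(frozen=True)
class GroupResult:
    """A group's CAPRI-style evaluation over a set of interfaces."""

    group: str
    per_interface: pd.DataFrame  # best_dockq, best_class, best_class_dockq
    class_counts: Mapping[str, int]
    weighted_score: int
    cumulative_dockq: float
    cumulative_dockq_class_best: float


def select_top_k(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k highest-confidence records of one target, descending.

    Ties break by stable input order; fewer than k records are returned
    whole.  The input must share a single target.
    """
    if records.empty:
        raise EmptyPoolError("cannot select from an empty record pool")
    targets = records["target"].unique()
    if len(targets) != 1:
        raise ValueError(f"select_top_k expects one target, got {list(targets)}")
    conf = ranking_confidence_frame(records).to_numpy()
    order = np.argsort(-conf, kind="stable")[:k]
    out = records.iloc[order].copy()
    out["ranking_confidence"] = conf[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_submissions(records: pd.DataFrame, k: int = 5,
                       group: str = "top-confidence") -> list[Submission]:
    """Per-target top-k selection over a multi-target record table."""
    if records.empty:
        raise EmptyPoolError("cannot select from an empty record pool")
    return [Submission(group, str(target), select_top_k(sub, k))
            for target, sub in records.groupby("target", sort=False)]


def _scored(scores: pd.DataFrame) -> pd.DataFrame:
    if "_class" in scores.columns:
        return scores
    return scores.assign(_class=effective_classes(scores))


def _aggregate(per_interface: pd.DataFrame, group: str) -> GroupResult:
    counts = {c: int((per_interface["best_class"] == c).sum()) for c in CAPRI_CLASSES}
    weighted = sum(CLASS_WEIGHTS[c] * counts[c] for c in CAPRI_CLASSES)
    return GroupResult(
        group=group,
        per_interface=per_interface,
        class_counts=counts,
        weighted_score=int(weighted),
        cumulative_dockq=float(per_interface["best_dockq"].sum()),
        cumulative_dockq_class_best=float(per_interface["best_class_dockq"].sum()),
    )


def _best_table(merged: pd.DataFrame) -> pd.DataFrame:
    """Per-interface best DockQ / best class / class-best DockQ."""
    merged = merged.assign(_rank=merged["_class"].map(CLASS_RANK))
    g = merged.groupby("interface", sort=False)
    out = g.agg(best_dockq=("dockq", "max"), _best_rank=("_rank", "max"))
    out["best_class"] = [CAPRI_CLASSES[r] for r in out["_best_rank"]]
    at_best = merged.loc[merged["_rank"].to_numpy()
                         == out["_best_rank"].reindex(merged["interface"]).to_numpy()]
    out["best_class_dockq"] = at_best.groupby("interface", sort=False)["dockq"].max()
    return out.drop(columns="_best_rank")


def evaluate_group(submissions: Sequence[Submission],
                   scores: pd.DataFrame, group: str | None = None) -> GroupResult:
    """Evaluate submissions against interface scores.

    Every submitted model must have a score at each assessed interface of its
    target; a submitted model without one raises :class:`MissingScoreError`.
    """
    if not submissions:
        raise EmptyPoolError("no submissions to evaluate")
    if group is None:
        group = submissions[0].group
    scored = _scored(scores)
    picks = pd.concat([s.models[KEY_COLUMNS] for s in submissions], ignore_index=True)

    merged = picks.merge(scored, on=KEY_COLUMNS, how="left", indicator=True)
    unmatched = merged["_merge"] == "left_only"
    if unmatched.any():
        bad = merged.loc[unmatched, KEY_COLUMNS].iloc[0].to_dict()
        raise MissingScoreError(f"submitted model has no interface score: {bad}")
    # a pick must be scored at every assessed interface of its target
    n_ifaces = scored.groupby("target")["interface"].nunique()
    per_pick = merged.groupby(KEY_COLUMNS, sort=False).size().reset_index(name="n")
    short = per_pick["n"] < per_pick["target"].map(n_ifaces).to_numpy()
    if short.any():
        bad = per_pick.loc[short, KEY_COLUMNS].iloc[0].to_dict()
        raise MissingScoreError(f"submitted model lacks a score at some interface: {bad}")
    return _aggregate(_best_table(merged), group)


def rank_groups(results: Sequence[GroupResult]) -> list[GroupResult]:
    """Order groups: weighted score desc, cumulative DockQ desc, name asc."""
    if not results:
        raise EmptyPoolError("no group results to rank")
    return sorted(results, key=lambda r: (-r.weighted_score, -r.cumulative_dockq, r.group))


def leaderboard_frame(results: Sequence[GroupResult]) -> pd.DataFrame:
    """Ranked one-row-per-group table (weighted score, counts, cumulative DockQ)."""
    rows = []
    for res in rank_groups(results):
        row = {"group": res.group, "weighted_score": res.weighted_score,
               "cumulative_dockq": res.cumulative_dockq}
        for c in CAPRI_CLASSES:
            row[f"n_{c}"] = res.class_counts.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def baseline_pseudogroups(records: pd.DataFrame, scores: pd.DataFrame,
                          baseline_records: pd.DataFrame,
                          baseline_scores: pd.DataFrame,
                          k: int = 5) -> dict[str, GroupResult]:
    """The four reference pseudo-groups for a clash-filtered pool.

    ``MassiveFold-best`` and ``AF2-baseline-best`` are oracle selections
    (best DockQ per interface over the pool / baseline); ``AF2-baseline``
    submits each target's max-ipTM baseline model; ``top-confidence``
    submits the per-target top-k by ranking confidence.
    """
    pool_scored = _scored(scores)
    base_scored = _scored(baseline_scores)

    oracle_pool = _aggregate(_best_table(pool_scored), "MassiveFold-best")
    oracle_base = _aggregate(_best_table(base_scored), "AF2-baseline-best")

    # one max-ipTM pick per target, stable first on ties
    picks = []
    for target, sub in baseline_records.groupby("target", sort=False):
        i = int(np.argmax(sub["iptm"].to_numpy()))
        picks.append(Submission("AF2-baseline", str(target), sub.iloc[[i]]))
    max_iptm = evaluate_group(picks, base_scored)

    brysbaert = evaluate_group(select_submissions(records, k=k), pool_scored)

    return {r.group: r for r in (oracle_pool, oracle_base, max_iptm, brysbaert)}
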