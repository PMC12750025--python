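"""Sampling-plan arithmetic, ranking confidence, clash filtering and I/O."""

import json

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, strategies as st

from foldpool.errors import (
    ConfigError,
    FormatError,
    MissingScoreError,
    SchemaError,
    TableValidationError,
)
from foldpool.store import (
    KEPT_SETS,
    REMOVED_SETS,
    ParameterSet,
    SamplingPlan,
    af2_baseline_plan,
    filter_clashes,
    monomer_plan,
    plan_from_yaml,
    plan_size,
    plan_to_yaml,
    ranking_confidence,
    ranking_confidence_frame,
    read_af_ranking_scores,
    read_prediction_table,
    reduced_multimer_plan,
    standard_multimer_plan,
    write_af_ranking_scores,
    write_prediction_table,
)


class TestPlans:
    @pytest.mark.parametrize("plan, expected", [
        (standard_multimer_plan(), 8040),           # 8 x 15 x 67
        (reduced_multimer_plan(), 2475),            # 5 x 15 x 33
        (standard_multimer_plan(33), 3960),         # 8 x 15 x 33
        (monomer_plan(), 8040),                     # 8 x 5 x 201
        (af2_baseline_plan(), 25),                  # one default run
    ])
    def test_plan_sizes(self, plan, expected):
        assert plan_size(plan) == expected

    def test_each_multimer_set_yields_1005(self):
        for ps in standard_multimer_plan():
            assert ps.size == 1005

    def test_monomer_samples_per_model(self):
        # only 5 NN models exist for monomers, so 201 samples keep 1005/set
        for ps in monomer_plan():
            assert ps.n_nn_models == 5
            assert ps.samples_per_model == 201

    def test_reduced_plan_drops_the_three_weak_sets(self):
        names = reduced_multimer_plan().set_names
        assert names == KEPT_SETS
        assert not set(REMOVED_SETS) & set(names)

    @given(st.lists(st.tuples(st.integers(1, 20), st.integers(1, 80)),
                    min_size=1, max_size=6),
           st.randoms(use_true_random=False))
    def test_plan_size_additive_and_order_invariant(self, shapes, rnd):
        sets = tuple(ParameterSet(f"s{i}", n_nn_models=m, samples_per_model=k)
                     for i, (m, k) in enumerate(shapes))
        total = plan_size(SamplingPlan("p", sets))
        assert total == sum(m * k for m, k in shapes)
        shuffled = list(sets)
        rnd.shuffle(shuffled)
        assert plan_size(SamplingPlan("q", tuple(shuffled))) == total

    def test_duplicate_set_names_rejected(self):
        ps = ParameterSet("a")
        with pytest.raises(ConfigError):
            SamplingPlan("p", (ps, ps))

    def test_plan_yaml_round_trip(self, tmp_path):
        plan = reduced_multimer_plan()
        plan_to_yaml(plan, tmp_path / "plan.yaml")
        assert plan_from_yaml(tmp_path / "plan.yaml") == plan


class TestRankingConfidence:
    @pytest.mark.parametrize("iptm, ptm, expected", [
        (0.5, 0.5, 0.5),     # fixed point of the convex combination
        (1.0, 1.0, 1.0),
        (0.9, 0.8, 0.88),
        (0.0, 0.0, 0.0),
        (0.25, 0.75, 0.35),
    ])
    def test_multimer_formula(self, iptm, ptm, expected):
        assert ranking_confidence(iptm=iptm, ptm=ptm) == pytest.approx(expected)

    def test_monomer_uses_mean_plddt(self):
        assert ranking_confidence(mean_plddt=87.5) == 87.5

    def test_missing_scores_raise(self):
        with pytest.raises(MissingScoreError):
            ranking_confidence()
        with pytest.raises(MissingScoreError):
            ranking_confidence(iptm=0.5)  # ptm absent

    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.001, 0.5), st.floats(0.001, 0.5))
    def test_strictly_increasing_in_each_score(self, iptm, ptm, di, dp):
        base = ranking_confidence(iptm=iptm, ptm=ptm)
        if iptm + di <= 1:
            assert ranking_confidence(iptm=iptm + di, ptm=ptm) > base
        if ptm + dp <= 1:
            assert ranking_confidence(iptm=iptm, ptm=ptm + dp) > base

    def test_frame_matches_scalar(self):
        df = pd.DataFrame({"iptm": [0.9, np.nan], "ptm": [0.8, np.nan],
                           "mean_plddt": [np.nan, 91.0]})
        conf = ranking_confidence_frame(df)
        assert conf.tolist() == pytest.approx([0.88, 91.0])


def _records(n_clashes, flags):
    n = len(n_clashes)
    return pd.DataFrame({
        "target": "T1", "parameter_set": "s", "nn_model": "m",
        "sample_index": range(n), "iptm": 0.5, "ptm": 0.5,
        "mean_plddt": np.nan, "n_clashes": n_clashes, "capri_clash_flag": flags,
    })


class TestClashFilter:
    def test_cutoff_is_strictly_more_than_300(self):
        recs = _records([300, 301], [False, False])
        retained, excluded = filter_clashes(recs)
        assert retained["sample_index"].tolist() == [0]
        assert excluded["reason"].tolist() == ["n_clashes>300"]

    def test_clean_pool_passes_unchanged(self):
        recs = _records([0] * 5, [False] * 5)
        retained, excluded = filter_clashes(recs)
        assert len(retained) == 5 and excluded.empty

    def test_capri_flag_alone_excludes(self):
        recs = _records([0, 0], [True, False])
        retained, excluded = filter_clashes(recs)
        assert retained["sample_index"].tolist() == [1]
        assert excluded["reason"].tolist() == ["capri_clash"]

    def test_against_brute_force_recount(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 600, 100)
        flags = rng.random(100) < 0.3
        retained, excluded = filter_clashes(_records(counts, flags))
        expected = sum(1 for c, f in zip(counts, flags) if c <= 300 and not f)
        assert len(retained) == expected
        assert len(retained) + len(excluded) == 100
        # reasons partition the removed set
        assert excluded["reason"].isin(["n_clashes>300", "capri_clash"]).all()

    def test_missing_clash_counts_treated_as_zero(self, caplog):
        recs = _records([0, 0], [False, False]).drop(columns="n_clashes")
        with caplog.at_level("WARNING"):
            retained, _ = filter_clashes(recs)
        assert len(retained) == 2


class TestPredictionTable:
    def _wide_fixture(self, tmp_path, dockq_t1=(0.2, 0.5, 0.9)):
        df = pd.DataFrame({
            "target": "T1", "parameter_set": "afm_basic", "nn_model": "m1",
            "sample_index": [0, 1, 2], "iptm": [0.4, 0.6, 0.8],
            "ptm": [0.5, 0.7, 0.9], "n_clashes": [0, 0, 0],
            "capri_clash_flag": [False, False, False],
            "dockq:T1.1": dockq_t1, "dockq:T1.2": [0.1, 0.3, 0.6],
        })
        path = tmp_path / "pool_T1.csv"
        df.to_csv(path, index=False)
        return path

    def test_counts_three_rows_two_interfaces(self, tmp_path):
        records, scores = read_prediction_table(self._wide_fixture(tmp_path))
        assert len(records) == 3
        assert len(scores) == 6
        assert set(scores["interface"]) == {"T1.1", "T1.2"}

    def test_out_of_range_dockq_names_row(self, tmp_path):
        path = self._wide_fixture(tmp_path, dockq_t1=(0.2, 1.2, 0.9))
        with pytest.raises(TableValidationError, match="row 3"):
            read_prediction_table(path)

    def test_missing_mandatory_column_named(self, tmp_path):
        df = pd.DataFrame({"target": ["T1"], "parameter_set": ["s"],
                           "nn_model": ["m"]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="sample_index"):
            read_prediction_table(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        df = pd.DataFrame({"target": ["T1"], "parameter_set": ["s"],
                           "nn_model": ["m"], "sample_index": [0],
                           "iptm": [0.5], "ptm": [0.5], "dockq:T1.1": [0.7]})
        path = tmp_path / "pool.tsv"
        df.to_csv(path, sep="\t", index=False)
        records, scores = read_prediction_table(path)
        assert len(records) == 1 and scores["dockq"].iloc[0] == 0.7

    def test_generated_pool_round_trips_exactly(self, small_benchmark, tmp_path):
        target = small_benchmark.records["target"].iloc[0]
        recs = small_benchmark.records.query("target == @target").reset_index(drop=True)
        scs = small_benchmark.scores.query("target == @target").reset_index(drop=True)
        path = tmp_path / "pool.csv"
        write_prediction_table(recs, scs, path)
        records2, scores2 = read_prediction_table(path)
        pdt.assert_frame_equal(records2, recs)
        pdt.assert_frame_equal(scores2.sort_values(["interface", "sample_index"],
                                                   kind="stable").reset_index(drop=True),
                               scs.sort_values(["interface", "sample_index"],
                                               kind="stable").reset_index(drop=True))


class TestRankingScoreJSON:
    def test_multimer_round_trip(self, tmp_path):
        scores = {f"model_{i}": 0.5 + i / 100 for i in range(25)}
        path = tmp_path / "ranking_debug.json"
        write_af_ranking_scores(scores, "multimer", path)
        loaded, dialect = read_af_ranking_scores(path)
        assert dialect == "multimer"
        assert loaded == scores
        assert list(loaded) == list(scores)  # order preserved

    def test_order_naming_unknown_model_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"iptm+ptm": {"a": 0.5}, "order": ["a", "b"]}))
        with pytest.raises(FormatError, match="b"):
            read_af_ranking_scores(path)

    @pytest.mark.parametrize("doc", [
        {"iptm+ptm": {"a": 0.5}, "plddts": {"a": 80.0}, "order": ["a"]},
        {"order": ["a"]},
    ])
    def test_ambiguous_or_missing_dialect_rejected(self, tmp_path, doc):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(FormatError):
            read_af_ranking_scores(path)

    def test_monomer_dialect_detected(self, tmp_path):
        path = tmp_path / "mono.json"
        write_af_ranking_scores({"m1": 91.2}, "monomer", path)
        _, dialect = read_af_ranking_scores(path)
        assert dialect == "monomer"
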