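import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmem.instance_model import ValidationError
from wmem.sga_preprocess import (
    CohortData,
    build_cover_instance,
    call_valid_sga,
    compute_weights,
    filter_rare_genes,
    fold_changes,
    hypergeom_upper_tail,
    partition_tumors,
    select_candidates,
    SignaturePartition,
    GeneWeight,
)


def hypergeom_tail_oracle(N, K, n, k):
    """Direct summation of the upper-tail formula."""
    total = 0
    for i in range(max(k, 0), min(n, K) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def make_cohort(mutation, gistic, expression, normals):
    """Small cohort from dicts keyed by gene; columns named T*/N*."""
    mut = pd.DataFrame(mutation).T
    gis = pd.DataFrame(gistic).T
    expr = pd.DataFrame(expression).T
    samples = list(expr.columns)
    types = ["normal" if s in normals else "tumor" for s in samples]
    return CohortData(mut, gis, expr, pd.Series(types, index=samples))


@pytest.fixture
def small_cohort():
    tumors = [f"T{i}" for i in range(8)]
    normals = ["N0", "N1"]
    # gene G1: mutation in T0; amplification in T1 (high expr) and T2 (low)
    mutation = {"G1": {t: 0 for t in tumors}}
    mutation["G1"]["T0"] = 1
    gistic = {"G1": {t: 0 for t in tumors}}
    gistic["G1"]["T1"] = 2
    gistic["G1"]["T2"] = 2
    gistic["G1"]["T3"] = -2
    expr = {"G1": {}}
    # GISTIC-0 background tumors are T0 and T4..T7
    bg = {"T0": 10.0, "T4": 8.70578, "T5": 9.56859, "T6": 10.43141, "T7": 11.29422}
    for t, v in bg.items():
        expr["G1"][t] = v
    mean = float(np.mean(list(bg.values())))
    sd = float(np.std(list(bg.values()), ddof=1))
    expr["G1"]["T1"] = mean + 1.64 * sd  # z exactly at threshold
    expr["G1"]["T2"] = mean + 1.50 * sd  # below threshold
    expr["G1"]["T3"] = mean - 1.70 * sd  # deletion, below -1.64
    expr["G1"]["N0"] = 10.0
    expr["G1"]["N1"] = 10.0
    return make_cohort(mutation, gistic, expr, normals)


class TestCallValidSGA:
    def test_mutation_always_valid(self, small_cohort):
        sga = call_valid_sga(small_cohort)
        assert "T0" in sga["G1"]

    def test_z_exactly_at_threshold_is_valid(self, small_cohort):
        sga = call_valid_sga(small_cohort)
        assert "T1" in sga["G1"]

    def test_z_below_threshold_not_valid(self, small_cohort):
        sga = call_valid_sga(small_cohort)
        assert "T2" not in sga["G1"]

    def test_deletion_with_low_z_valid(self, small_cohort):
        sga = call_valid_sga(small_cohort)
        assert "T3" in sga["G1"]

    def test_zero_spread_background_skips_cnv(self):
        tumors = [f"T{i}" for i in range(5)]
        gistic = {"G1": {t: 0 for t in tumors}}
        gistic["G1"]["T0"] = 2
        expr = {"G1": {t: 10.0 for t in tumors}}
        expr["G1"]["N0"] = 10.0
        mutation = {"G1": {t: 0 for t in tumors}}
        mutation["G1"]["T1"] = 1
        cohort = make_cohort(mutation, gistic, expr, ["N0"])
        sga = call_valid_sga(cohort)
        assert sga == {"G1": frozenset({"T1"})}  # mutation channel unaffected

    def test_gistic_pm1_ignored(self):
        tumors = [f"T{i}" for i in range(6)]
        gistic = {"G1": {t: 0 for t in tumors}}
        gistic["G1"]["T0"] = 1
        gistic["G1"]["T1"] = -1
        expr = {"G1": {t: float(10 + i) for i, t in enumerate(tumors)}}
        expr["G1"]["N0"] = 10.0
        mutation = {"G1": {t: 0 for t in tumors}}
        cohort = make_cohort(mutation, gistic, expr, ["N0"])
        assert call_valid_sga(cohort) == {}


class TestFilterRareGenes:
    def test_five_tumors_removed(self):
        sga = {"G": frozenset(f"T{i}" for i in range(5))}
        assert filter_rare_genes(sga) == {}

    def test_six_tumors_kept(self):
        sga = {"G": frozenset(f"T{i}" for i in range(6))}
        assert filter_rare_genes(sga) == sga

    def test_empty(self):
        assert filter_rare_genes({}) == {}


class TestFoldChanges:
    def _folds(self, tumor_value, normal_values, pseudocount=0.0):
        expr = pd.DataFrame(
            {"T0": [tumor_value], **{f"N{i}": [v] for i, v in enumerate(normal_values)}},
            index=["G"],
        )
        types = pd.Series(
            ["tumor"] + ["normal"] * len(normal_values),
            index=["T0"] + [f"N{i}" for i in range(len(normal_values))],
        )
        return fold_changes(expr, types, pseudocount=pseudocount)

    def test_threefold_up(self):
        assert self._folds(30.0, [10.0]).loc["G", "T0"] == pytest.approx(3.0)

    def test_identity(self):
        assert self._folds(10.0, [10.0]).loc["G", "T0"] == pytest.approx(1.0)

    def test_below_twofold(self):
        f = self._folds(19.0, [10.0]).loc["G", "T0"]
        assert f == pytest.approx(1.9)
        assert f < 2.0

    def test_median_of_normals(self):
        f = self._folds(20.0, [5.0, 10.0, 100.0]).loc["G", "T0"]
        assert f == pytest.approx(2.0)  # median(5,10,100)=10

    def test_pseudocount_prevents_division_error(self):
        f = self._folds(0.0, [0.0], pseudocount=1.0).loc["G", "T0"]
        assert f == pytest.approx(1.0)

    def test_zero_reference_zero_pseudocount_errors(self):
        with pytest.raises(ValidationError):
            self._folds(1.0, [0.0], pseudocount=0.0)

    def test_log2_input_unlogged(self):
        expr = pd.DataFrame({"T0": [5.0], "N0": [3.0]}, index=["G"])
        types = pd.Series(["tumor", "normal"], index=["T0", "N0"])
        f = fold_changes(expr, types, pseudocount=0.0, log2_input=True)
        assert f.loc["G", "T0"] == pytest.approx(4.0)  # 32/8


def folds_frame(values):
    """genes x tumors fold table from {gene: {tumor: fold}}."""
    return pd.DataFrame(values).T


class TestPartitionTumors:
    def test_100_percent_up_joins_sp(self):
        folds = folds_frame({f"g{i}": {"T0": 4.0} for i in range(4)})
        part = partition_tumors("sig", [f"g{i}" for i in range(4)], folds, min_sp_size=0)
        assert "T0" in part.sp
        assert part.direction["T0"] == "up"

    def test_exactly_75_percent_not_sp(self):
        vals = {f"g{i}": {"T0": 4.0} for i in range(3)}
        vals["g3"] = {"T0": 1.0}
        part = partition_tumors("sig", [f"g{i}" for i in range(4)], folds_frame(vals), min_sp_size=0)
        assert "T0" not in part.sp

    def test_50_percent_small_changes_joins_sn(self):
        vals = {
            "g0": {"T0": 1.1},
            "g1": {"T0": 1.5},
            "g2": {"T0": 2.5},
            "g3": {"T0": 2.5},
        }
        part = partition_tumors("sig", list(vals), folds_frame(vals), min_sp_size=0)
        assert "T0" in part.sn

    def test_down_regulated_sp(self):
        folds = folds_frame({f"g{i}": {"T0": 0.2} for i in range(4)})
        part = partition_tumors("sig", [f"g{i}" for i in range(4)], folds, min_sp_size=0)
        assert "T0" in part.sp
        assert part.direction["T0"] == "down"

    def _mixed_partition(self, n_up, n_down, min_sp_size=0):
        genes = ["g0", "g1"]
        vals = {g: {} for g in genes}
        for i in range(n_up):
            for g in genes:
                vals[g][f"U{i}"] = 4.0
        for i in range(n_down):
            for g in genes:
                vals[g][f"D{i}"] = 0.2
        return partition_tumors("sig", genes, folds_frame(vals), min_sp_size=min_sp_size)

    def test_small_subgroup_dropped(self):
        part = self._mixed_partition(100, 9)
        assert part.accepted
        assert len(part.sp) == 100
        assert all(part.direction[t] == "up" for t in part.sp)

    def test_comparable_subgroups_reject_signature(self):
        part = self._mixed_partition(100, 20)
        assert not part.accepted
        assert "sub-group" in part.reason

    def test_sp_exactly_30_rejected(self):
        part = self._mixed_partition(30, 0, min_sp_size=30)
        assert not part.accepted
        assert "S_p" in part.reason

    def test_sp_31_accepted(self):
        part = self._mixed_partition(31, 0, min_sp_size=30)
        assert part.accepted

    def test_sp_sn_disjoint(self):
        part = self._mixed_partition(40, 3)
        assert not (part.sp & part.sn)

    def test_empty_signature_errors(self):
        with pytest.raises(ValidationError):
            partition_tumors("sig", [], folds_frame({"g": {"T0": 1.0}}))

    def test_missing_genes_dropped_from_denominator(self):
        folds = folds_frame({"g0": {"T0": 4.0}})
        part = partition_tumors("sig", ["g0", "ghost"], folds, min_sp_size=0)
        assert "T0" in part.sp  # 1/1 genes present is > 75%


def accepted_partition(sp, sn):
    return SignaturePartition("sig", frozenset(sp), frozenset(sn),
                              {t: "up" for t in sp}, "accepted", None)


class TestComputeWeights:
    def test_matches_direct_tail_and_ordering(self):
        sp = [f"P{i}" for i in range(30)]
        sn = [f"Q{i}" for i in range(70)]
        part = accepted_partition(sp, sn)
        sga = {
            "g1": frozenset(sp[:10] + sn[:2]),   # k=10 of n=12
            "g2": frozenset(sp[:10] + sn[:20]),  # k=10 of n=30
        }
        weights = {gw.gene: gw for gw in compute_weights(sga, part)}
        w1 = hypergeom_tail_oracle(100, 30, 12, 10)
        w2 = hypergeom_tail_oracle(100, 30, 30, 10)
        assert weights["g1"].weight == pytest.approx(w1, rel=1e-10)
        assert weights["g2"].weight == pytest.approx(w2, rel=1e-10)
        assert weights["g1"].weight < weights["g2"].weight
        assert weights["g1"].k_p == 10 and weights["g1"].k_n == 2

    def test_k_zero_weight_one(self):
        part = accepted_partition(["P0", "P1"], ["Q0", "Q1"])
        sga = {"g": frozenset(["Q0", "Q1"])}
        (gw,) = compute_weights(sga, part)
        assert gw.weight == 1.0

    def test_certain_event_weight_one(self):
        part = accepted_partition(["P0", "P1"], [])
        sga = {"g": frozenset(["P0", "P1"])}
        (gw,) = compute_weights(sga, part)
        assert gw.weight == 1.0

    def test_events_outside_partition_skipped(self):
        part = accepted_partition(["P0"], ["Q0"])
        sga = {"g": frozenset(["elsewhere"])}
        assert compute_weights(sga, part) == []

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_monotonicity(self, data):
        K = data.draw(st.integers(2, 15))
        N = K + data.draw(st.integers(2, 15))
        n = data.draw(st.integers(1, N - 1))
        k = data.draw(st.integers(0, min(n, K)))
        w = hypergeom_upper_tail(N, K, n, k)
        assert 0.0 <= w <= 1.0
        # non-increasing in k
        if k + 1 <= min(n, K):
            assert hypergeom_upper_tail(N, K, n, k + 1) <= w + 1e-12
        # non-decreasing in n with k fixed
        if n + 1 <= N and k <= min(n + 1, K):
            assert hypergeom_upper_tail(N, K, n + 1, k) >= w - 1e-12

    def test_matches_oracle_grid(self):
        for N, K, n, k in [(10, 4, 3, 2), (20, 5, 8, 0), (12, 6, 6, 6), (9, 3, 4, 1)]:
            assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), rel=1e-10
            )


class TestSelectCandidates:
    def _weights(self, values):
        return [GeneWeight(f"g{i:03d}", 1, 0, w) for i, w in enumerate(values)]

    def test_truncates_to_top_k(self):
        weights = self._weights([0.001 * i for i in range(250)])
        out = select_candidates(weights, top_k=200, max_weight=0.2)
        assert len(out) == 200
        assert out[0] == "g000"

    def test_all_kept_when_fewer(self):
        weights = self._weights([0.001 * i for i in range(150)])
        assert len(select_candidates(weights)) == 150

    def test_exactly_point_two_excluded(self):
        weights = [GeneWeight("g", 1, 0, 0.2)]
        assert select_candidates(weights) == []

    def test_sorted_by_weight_then_gene(self):
        weights = [GeneWeight("b", 1, 0, 0.1), GeneWeight("a", 1, 0, 0.1),
                   GeneWeight("c", 1, 0, 0.05)]
        assert select_candidates(weights) == ["c", "a", "b"]


class TestBuildCoverInstance:
    def test_worked_example_shape(self):
        part = accepted_partition([f"T{i}" for i in range(1, 6)], [])
        sga = {
            "g1": frozenset({"T1", "T2"}),
            "g2": frozenset({"T2", "T3", "T4"}),
            "g3": frozenset({"T2", "T5"}),
        }
        weights = [GeneWeight("g1", 2, 0, 0.01), GeneWeight("g2", 3, 0, 0.02),
                   GeneWeight("g3", 2, 0, 0.03)]
        inst = build_cover_instance(part, sga, weights, ["g1", "g2", "g3"])
        assert inst.universe == frozenset({"T1", "T2", "T3", "T4", "T5"})
        smap = inst.set_map()
        assert smap["g1"].elements == frozenset({"T1", "T2"})
        assert smap["g2"].elements == frozenset({"T2", "T3", "T4"})
        assert smap["g3"].elements == frozenset({"T2", "T5"})
        assert smap["g2"].weight == 0.02

    def test_candidate_with_all_events_in_sn_dropped(self):
        part = accepted_partition(["T1"], ["T2"])
        sga = {"g": frozenset({"T2"})}
        inst = build_cover_instance(part, sga, [GeneWeight("g", 0, 1, 0.1)], ["g"])
        assert inst.m == 0

    def test_no_candidates_empty_instance(self):
        part = accepted_partition(["T1"], [])
        inst = build_cover_instance(part, {}, [], [])
        assert inst.m == 0
        assert inst.universe == frozenset({"T1"})


class TestPipelineIdempotence:
    def test_repeat_runs_identical(self, small_cohort):
        runs = []
        for _ in range(2):
            sga = call_valid_sga(small_cohort)
            folds = fold_changes(small_cohort.expression, small_cohort.sample_type)
            runs.append((sga, folds.to_csv()))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
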