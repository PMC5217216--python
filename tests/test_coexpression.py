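"""Pearson cutoff sets, Venn cores, gene mapping and consensus."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spudcoex import ParamSet, SimConfig, generate
from spudcoex.coexpression import (
    CoexpressionError,
    UndefinedCorrelationError,
    coexpressed_set,
    correlate_with_feature,
    cross_platform_consensus,
    entities_to_genes,
    evaluate_recovery,
    pearson,
    pearson_pvalue,
    platform_core,
)
from spudcoex.preprocess import ExpressionMatrix
from _oracles import pearson_pvalue_oracle, pearson_two_pass


def _mat(arr, platform="arrayA"):
    arr = np.asarray(arr, float)
    df = pd.DataFrame(arr, index=[f"e{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    return ExpressionMatrix(platform, "log2_norm", df)


class TestPearson:
    def test_known_values(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == 1.0
        assert pearson([1, 2, 3], [3, 2, 1]) == -1.0
        # Hand computation: sum dx dy = 4, sum dx^2 = sum dy^2 = 5.
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == 0.8

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert pearson(x, y) == pytest.approx(pearson(y, x), abs=1e-15)
        assert pearson(3.0 * x + 7.0, y) == pytest.approx(pearson(x, y),
                                                          abs=1e-12)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 100.0, 8.0, 10.0]
        assert pearson(x, y) == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_raises(self):
        with pytest.raises(CoexpressionError):
            pearson([1.0, np.nan, 3.0], [1.0, 2.0, np.nan], min_pairs=3)


class TestPearsonPvalue:
    def test_spot_values(self):
        assert pearson_pvalue(0.0, 10) == pytest.approx(1.0)
        assert pearson_pvalue(1.0, 4) == 0.0
        assert pearson_pvalue(0.8, 5) == pytest.approx(0.104, abs=1e-3)

    @pytest.mark.parametrize("r,n", [(0.0, 10), (0.8, 5), (-0.5, 8),
                                     (0.3, 30), (0.95, 4)])
    def test_matches_integration_oracle(self, r, n):
        assert pearson_pvalue(r, n) == pytest.approx(
            pearson_pvalue_oracle(r, n), abs=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(CoexpressionError):
            pearson_pvalue(0.5, 2)


class TestCorrelateWithFeature:
    def test_matches_two_pass_oracle(self, rng):
        m = _mat(rng.normal(size=(200, 30)))
        r = correlate_with_feature(m, "e0")
        for i in range(200):
            expect = 1.0 if i == 0 else pearson_two_pass(
                m.values.iloc[i], m.values.iloc[0])
            assert abs(r.iloc[i] - expect) < 1e-12

    def test_handles_missing_values(self, rng):
        arr = rng.normal(size=(20, 10))
        arr[3, 4] = np.nan
        m = _mat(arr)
        r = correlate_with_feature(m, "e0")
        expect = pearson(arr[3], arr[0])
        assert r["e3"] == pytest.approx(expect, abs=1e-12)

    def test_absent_feature_named_in_error(self, rng):
        m = _mat(rng.normal(size=(4, 6)))
        with pytest.raises(CoexpressionError, match="nope"):
            correlate_with_feature(m, "nope")


class TestCoexpressedSet:
    def test_exact_cutoff_value_retained(self, params):
        # r(e0, e1) is exactly 0.8 by construction.
        m = _mat([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0],
                  [4.0, 3.0, 2.0, 1.0]])
        core, per = coexpressed_set(m, ["e0"], params)
        assert core == {"e0", "e1"}

    def test_intersection_over_query_probes(self, params):
        n = 40
        rng = np.random.default_rng(0)
        base = rng.normal(size=n)
        probe_a = base + rng.normal(0, 0.05, n)
        probe_b = base + rng.normal(0, 0.05, n)
        near = base + rng.normal(0, 0.45, n)   # high r to one probe only
        rows = np.vstack([probe_a, probe_b, near])
        m = _mat(rows)
        r_a = pearson(near, probe_a)
        r_b = pearson(near, probe_b)
        params2 = ParamSet(pcc_cutoff=min(r_a, r_b) + 1e-6)
        core, per = coexpressed_set(m, ["e0", "e1"], params2)
        assert "e2" not in core  # fails the weaker of the two probes
        assert per["e0" if r_a > r_b else "e1"].issuperset({"e2"})

    def test_matches_bruteforce_scan(self, params, rng):
        m = _mat(rng.normal(size=(120, 15)))
        params2 = ParamSet(pcc_cutoff=0.35)
        core, per = coexpressed_set(m, ["e0", "e1"], params2)
        for f in ("e0", "e1"):
            brute = {g for g in m.feature_ids
                     if pearson(m.values.loc[g], m.values.loc[f])
                     >= params2.pcc_cutoff}
            assert per[f] == brute
        assert core == per["e0"] & per["e1"]

    def test_query_feature_in_its_own_set(self, params, rng):
        m = _mat(rng.normal(size=(10, 8)))
        core, per = coexpressed_set(m, ["e4"], params)
        assert "e4" in per["e4"]


class TestPlatformCore:
    def test_central_intersection(self):
        sets = {"q1": {"a", "b", "c"}, "q2": {"b", "c", "d"}, "q3": {"c", "e"}}
        core, regions = platform_core(sets)
        assert core == {"c"}
        assert regions["q1&q2&q3"] == 1

    def test_single_set_is_its_own_core(self):
        core, regions = platform_core({"q": {"x", "y"}})
        assert core == {"x", "y"}
        assert regions == {"q": 2}

    def test_regions_satisfy_inclusion_exclusion(self, rng):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"q{k}": {g for g in universe if rng.random() < 0.5}
                for k in range(3)}
        _, regions = platform_core(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        for k in range(1, 4):
            for combo in itertools.combinations(sorted(sets), k):
                inside = set.intersection(*(sets[q] for q in combo))
                outside = set().union(*(sets[q] for q in sets
                                        if q not in combo)) if k < 3 else set()
                assert regions["&".join(combo)] == len(inside - outside)


class TestEntityMapping:
    def _table(self):
        rows = [("p1", "g1", False), ("p2", "g1", False), ("p3", "g2", False),
                ("px", "g2", True), ("px", "g3", True)]
        return pd.DataFrame([{"probe_id": p, "platform": "arrayA",
                              "gene_id": g, "identity": 100.0,
                              "intron_overlap_bp": 0, "ambiguous": a,
                              "valid": True, "reason": "ok"}
                             for p, g, a in rows])

    def test_probes_collapse_to_genes(self):
        genes, amb, unmapped = entities_to_genes({"p1", "p2", "p3"},
                                                 self._table(), "arrayA")
        assert genes == {"g1", "g2"} and not amb and unmapped == 0

    def test_ambiguous_probe_contributes_all_genes_flagged(self):
        genes, amb, _ = entities_to_genes({"px"}, self._table(), "arrayA")
        assert genes == {"g2", "g3"} and amb == {"g2", "g3"}

    def test_unmapped_probe_dropped_and_counted(self):
        genes, _, unmapped = entities_to_genes({"p1", "zz"}, self._table(),
                                               "arrayA")
        assert genes == {"g1"} and unmapped == 1

    def test_gene_level_platform_is_identity(self):
        genes, amb, unmapped = entities_to_genes({"g7"}, None, "fpkm")
        assert genes == {"g7"} and not amb and unmapped == 0


class TestConsensus:
    def test_strict_intersection(self):
        res = cross_platform_consensus({"a": {"g1", "g2"}, "b": {"g2", "g3"},
                                        "c": {"g2"}})
        assert res.genes == ["g2"]

    def test_disjoint_sets_empty(self):
        res = cross_platform_consensus({"a": {"g1"}, "b": {"g2"}})
        assert res.genes == []

    def test_single_platform_rejected(self):
        with pytest.raises(CoexpressionError):
            cross_platform_consensus({"a": {"g1"}})

    def test_recovery_metrics_arithmetic(self):
        metrics = evaluate_recovery(["q1", "m1", "m2", "x1"],
                                    ["q1", "m1", "m2", "m3", "m4"], ["q1"])
        assert metrics["precision"] == pytest.approx(2 / 3)
        assert metrics["recall"] == pytest.approx(2 / 4)
        assert metrics["f1"] == pytest.approx(2 * (2/3) * 0.5 / (2/3 + 0.5))

    def test_empty_truth_module_rejected(self):
        with pytest.raises(CoexpressionError):
            evaluate_recovery(["g"], ["q1"], ["q1"])


class TestMonotonicity:
    def test_raising_cutoff_never_enlarges_set(self, rng):
        m = _mat(rng.normal(size=(60, 12)))
        prev = None
        for cutoff in (0.2, 0.4, 0.6, 0.8, 0.95):
            core, _ = coexpressed_set(m, ["e0"], ParamSet(pcc_cutoff=cutoff))
            if prev is not None:
                assert core <= prev
            prev = core

    def test_adding_query_never_enlarges_core(self, rng):
        m = _mat(rng.normal(size=(60, 12)))
        params = ParamSet(pcc_cutoff=0.3)
        queries = ["e0", "e1", "e2"]
        prev = None
        for k in range(1, 4):
            core, _ = coexpressed_set(m, queries[:k], params)
            if prev is not None:
                assert core <= prev
            prev = core

    def test_adding_platform_never_enlarges_consensus(self, rng):
        sets = {f"p{k}": {f"g{i}" for i in rng.choice(20, size=10,
                                                      replace=False)}
                for k in range(4)}
        prev = None
        for k in range(2, 5):
            sub = {p: sets[p] for p in list(sets)[:k]}
            res = cross_platform_consensus(sub)
            if prev is not None:
                assert set(res.genes) <= prev
            prev = set(res.genes)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_cutoff_monotonicity_property(self, seed):
        rng = np.random.default_rng(seed)
        m = _mat(rng.normal(size=(25, 8)))
        lo, _ = coexpressed_set(m, ["e0"], ParamSet(pcc_cutoff=0.5))
        hi, _ = coexpressed_set(m, ["e0"], ParamSet(pcc_cutoff=0.7))
        assert hi <= lo


class TestPlantedModuleRecovery:
    def test_noise_free_module_superset(self):
        cfg = dataclasses.replace(
            SimConfig(), n_genes=50, module_size=6,
            n_tissue_specific_leaf=0, n_tissue_specific_tuber=0,
            n_ramp_genes=0, noise_sd=0.0, probe_noise_sd=0.0,
            module_loading=1.0)
        sim = generate(cfg, seed=9)
        m = ExpressionMatrix("fpkm", "log2_norm",
                             np.log2(sim.matrices["fpkm"].values))
        q = sim.truth.query_genes[0]
        core, _ = coexpressed_set(m, [q], ParamSet())
        assert core >= set(sim.truth.module_genes)
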