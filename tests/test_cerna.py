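"""Shared-miRNA hypergeometric test and coexpression filter.

The tail probability is checked against a brute-force oracle that
enumerates every possible regulator subset, and against scipy's
hypergeometric survival function as an independent library route.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cerna_scope.cerna import (
    coexpression_filter,
    enumerate_candidates,
    pearson_with_p,
    shared_mirna_pvalue,
)
from cerna_scope.diffexpr import bh_adjust
from cerna_scope.io import ExpressionMatrix, InteractionTable


def brute_force_shared_pvalue(t: int, n: int, r: int, m: int) -> float:
    """P(overlap >= r) by enumerating all C(m, n) regulator subsets."""
    if r == 0:
        return 1.0
    target = set(range(t))
    hits = sum(
        1
        for sub in itertools.combinations(range(m), n)
        if len(target.intersection(sub)) >= r
    )
    return hits / math.comb(m, n)


def _table(rows, kind) -> InteractionTable:
    return InteractionTable(
        edges=pd.DataFrame(rows, columns=["mirna", "target"]), target_kind=kind
    )


class TestSharedMirnaPvalue:
    def test_zero_overlap_gives_p_one(self):
        assert shared_mirna_pvalue(t=3, n=4, r=0, m=10) == 1.0

    def test_degenerate_urn_gives_p_one(self):
        # every miRNA hits the mRNA, so observing r = n shared is certain
        assert shared_mirna_pvalue(t=20, n=7, r=7, m=20) == pytest.approx(1.0)

    def test_moderate_overlap_against_subset_enumeration(self):
        # (t=5, n=4, r=3, m=20): 155 of the 4845 4-subsets overlap >= 3
        expected = brute_force_shared_pvalue(5, 4, 3, 20)
        assert expected == pytest.approx(155 / 4845)
        assert shared_mirna_pvalue(5, 4, 3, 20) == pytest.approx(expected, rel=1e-12)

    def test_non_increasing_in_r(self):
        ps = [shared_mirna_pvalue(6, 5, r, 12) for r in range(6)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @given(st.integers(1, 40), st.data())
    def test_agrees_with_scipy_survival_function(self, m, data):
        t = data.draw(st.integers(0, m))
        n = data.draw(st.integers(0, m))
        r = data.draw(st.integers(0, min(t, n)))
        ours = shared_mirna_pvalue(t, n, r, m)
        theirs = float(stats.hypergeom.sf(r - 1, m, t, n))
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            shared_mirna_pvalue(t=5, n=4, r=5, m=20)
        with pytest.raises(ValueError):
            shared_mirna_pvalue(t=25, n=4, r=1, m=20)


class TestEnumerateCandidates:
    def test_single_shared_mirna(self):
        mm = _table([("M1", "G1")], "mRNA")
        ml = _table([("M1", "L1")], "lncRNA")
        cands = enumerate_candidates({"L1"}, {"G1"}, mm, ml)
        assert len(cands) == 1
        c = cands[0]
        assert (c.test.t, c.test.n, c.test.r) == (1, 1, 1)
        assert c.test.m == 1  # universe = union of tables
        assert c.shared_mirna_ids == {"M1"}

    def test_disjoint_regulators_give_no_candidates(self):
        mm = _table([("M1", "G1")], "mRNA")
        ml = _table([("M2", "L1")], "lncRNA")
        assert enumerate_candidates({"L1"}, {"G1"}, mm, ml) == []

    def test_empty_de_sets_give_empty_result(self):
        mm = _table([("M1", "G1")], "mRNA")
        ml = _table([("M1", "L1")], "lncRNA")
        assert enumerate_candidates(set(), {"G1"}, mm, ml) == []

    def test_fdr_is_bh_over_all_pairs(self):
        mm = _table(
            [("M1", "G1"), ("M2", "G1"), ("M1", "G2"), ("M3", "G2"), ("M4", "G3")],
            "mRNA",
        )
        ml = _table([("M1", "L1"), ("M2", "L1"), ("M3", "L2")], "lncRNA")
        cands = enumerate_candidates({"L1", "L2"}, {"G1", "G2", "G3"}, mm, ml)
        assert cands  # at least one overlapping pair
        fdrs = bh_adjust([c.test.p_value for c in cands])
        np.testing.assert_allclose([c.test.fdr for c in cands], fdrs)

    def test_planted_triplets_all_enumerated(self, small_study):
        truth = small_study.truth
        dels = set(truth.de_lncrnas)
        degs = set(truth.de_genes)
        cands = enumerate_candidates(
            dels, degs, small_study.mirna_mrna, small_study.mirna_lncrna
        )
        pairs = {(c.lncrna_id, c.mrna_id): c for c in cands}
        for trip in truth.planted_triplets:
            c = pairs[(trip.lncrna, trip.mrna)]
            assert c.test.r >= small_study.config.shared_mirnas_per_triplet

    def test_fixed_universe_mode(self):
        mm = _table([("M1", "G1")], "mRNA")
        ml = _table([("M1", "L1")], "lncRNA")
        c = enumerate_candidates(
            {"L1"}, {"G1"}, mm, ml, universe_mode="fixed", universe_size=100
        )[0]
        assert c.test.m == 100
        with pytest.raises(ValueError):
            enumerate_candidates({"L1"}, {"G1"}, mm, ml, universe_mode="fixed")


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_perfect_anticorrelation(self):
        x = np.arange(6.0)
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # x=1..6, y=(2,1,4,3,6,5): r = 14.5/17.5 = 29/35,
        # t = r sqrt(4/(1-r^2)), p two-sided on 4 df = 0.041563
        r, p = pearson_with_p([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert r == pytest.approx(29 / 35)
        assert p == pytest.approx(0.04156268221574339, rel=1e-6)

    def test_constant_vector_returns_nan(self):
        r, p = pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2, 3], [1, 2])


def _pair_matrix(case_lnc, case_mrna, ctrl_lnc, ctrl_mrna) -> ExpressionMatrix:
    """Two-feature matrix with prescribed log-scale values per group."""
    n_case, n_ctrl = len(case_lnc), len(ctrl_lnc)
    vals = np.vstack(
        [np.concatenate([case_lnc, ctrl_lnc]), np.concatenate([case_mrna, ctrl_mrna])]
    )
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    values = pd.DataFrame(np.expm1(vals).clip(0), index=["L1", "G1"], columns=samples)
    return ExpressionMatrix(
        values=values,
        feature_kind=pd.Series(["lncRNA", "gene"], index=["L1", "G1"]),
        group=pd.Series(
            ["case"] * n_case + ["control"] * n_ctrl, index=samples, name="group"
        ),
    )


def _one_candidate(fdr=0.001):
    from cerna_scope.cerna import CeRNACandidate, SharedMirnaTest

    return CeRNACandidate(
        lncrna_id="L1",
        mrna_id="G1",
        shared_mirna_ids=frozenset({"M1"}),
        test=SharedMirnaTest(m=50, t=5, n=5, r=1, p_value=fdr, fdr=fdr),
    )


class TestCoexpressionFilter:
    def _uncorrelated(self):
        rng = np.random.default_rng(1)
        return _pair_matrix(
            rng.normal(3, 1, 8), rng.normal(3, 1, 8),
            rng.normal(3, 1, 12), rng.normal(3, 1, 12),
        )

    def _case_correlated(self):
        rng = np.random.default_rng(2)
        f_case = rng.normal(0, 1, 10)
        return _pair_matrix(
            3 + f_case, 3 + f_case + rng.normal(0, 0.05, 10),
            rng.normal(3, 1, 12), rng.normal(3, 1, 12),
        )

    @pytest.mark.parametrize("mode", ["both_groups", "case_only", "delta"])
    def test_uncorrelated_pair_fails_every_mode(self, mode):
        out = coexpression_filter([_one_candidate()], self._uncorrelated(), mode=mode)
        assert not out[0].coexpr.passes and not out[0].accepted

    def test_case_gained_coexpression_mode_dependence(self):
        mat = self._case_correlated()
        for mode, expected in (("case_only", True), ("delta", True), ("both_groups", False)):
            out = coexpression_filter([_one_candidate()], mat, mode=mode)
            assert out[0].coexpr.passes is expected, mode

    def test_delta_threshold_arithmetic(self):
        # cor_case ~ 0.9, cor_control ~ 0.5 -> delta 0.4 < 0.5 fails
        rng = np.random.default_rng(3)
        f_case = rng.normal(0, 1, 40)
        f_ctrl = rng.normal(0, 1, 40)
        mat = _pair_matrix(
            3 + f_case, 3 + f_case + rng.normal(0, 0.5, 40),  # r ~ 0.9
            3 + f_ctrl, 3 + f_ctrl + rng.normal(0, 1.75, 40),  # r ~ 0.5
        )
        out = coexpression_filter([_one_candidate()], mat, mode="delta")
        rec = out[0].coexpr
        assert 0.75 < rec.cor_case
        assert rec.delta < 0.5
        assert not rec.passes

    def test_insignificant_hypergeometric_fdr_blocks_acceptance(self):
        out = coexpression_filter(
            [_one_candidate(fdr=0.5)], self._case_correlated(), mode="case_only"
        )
        assert out[0].coexpr.passes and not out[0].accepted

    def test_missing_feature_dropped_with_warning(self, caplog):
        cand = _one_candidate()
        cand.mrna_id = "ABSENT"
        out = coexpression_filter([cand], self._uncorrelated(), mode="case_only")
        assert out == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            coexpression_filter([], self._uncorrelated(), mode="sideways")
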