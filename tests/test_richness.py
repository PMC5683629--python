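"""Rarefaction, Chao2 and CI-overlap behaviour against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from barcodeaudit.richness import (IncidenceMatrix, RichnessEstimate, Z_84,
                                   bootstrap_chao2, build_incidence, chao2,
                                   chao2_point, ci_overlap, rarefaction)
from conftest import survey


def inc_from_bool(mat):
    mat = np.asarray(mat, dtype=bool)
    return IncidenceMatrix(pd.DataFrame(
        mat, index=[f"sp{i}" for i in range(mat.shape[0])],
        columns=[f"e{j}" for j in range(mat.shape[1])]))


def exhaustive_tau(inc, h):
    """Mean richness over all C(m, h) event subsets — brute-force oracle."""
    mat = inc.table.to_numpy()
    vals = [int((mat[:, list(sub)].any(axis=1)).sum())
            for sub in itertools.combinations(range(inc.m), h)]
    return sum(vals) / len(vals)


class TestIncidence:
    def test_basic_tally(self):
        records = [
            survey("a1", morpho="A", event="E1"), survey("a2", morpho="A", event="E2"),
            survey("a3", morpho="A", event="E3"), survey("b1", morpho="B", event="E2"),
        ]
        inc = build_incidence(records, lambda r: r.field_morphospecies)
        assert inc.s_obs == 2 and inc.m == 3
        assert sorted(inc.y) == [1, 3]
        assert inc.q1 == 1 and inc.q2 == 0

    def test_duplicates_collapse_to_single_incidence(self):
        records = [survey(f"x{i}", morpho="A", event="E1") for i in range(5)]
        records.append(survey("y", morpho="A", event="E2"))
        inc = build_incidence(records, lambda r: r.field_morphospecies)
        assert inc.s_obs == 1 and list(inc.y) == [2]

    def test_field_vs_otu_views_differ_under_splitting(self):
        # one true species field-split into two labels
        records = [survey("a", morpho="A1", event="E1"),
                   survey("b", morpho="A2", event="E2")]
        by_field = build_incidence(records, lambda r: r.field_morphospecies)
        by_otu = build_incidence(records, lambda r: "OTU1")
        assert by_field.s_obs == 2 and by_otu.s_obs == 1

    def test_no_events_error(self):
        with pytest.raises(ValueError, match="sampling events"):
            build_incidence([], lambda r: "x")


class TestRarefaction:
    def test_full_sample_equals_sobs(self, rng):
        mat = rng.random((12, 6)) < 0.4
        mat[:, 0] = True
        inc = inc_from_bool(mat)
        curve = rarefaction(inc)
        assert curve.at(inc.m).tau == pytest.approx(inc.s_obs)

    def test_hand_example_m3(self):
        # species A in all 3 events, B in one: subsets of 1 event have
        # richness 2,1,1 -> mean 4/3
        inc = inc_from_bool([[1, 1, 1], [0, 1, 0]])
        assert rarefaction(inc).at(1).tau == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_mean_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 9))
        mat = rng.random((int(rng.integers(4, 15)), m)) < rng.uniform(0.2, 0.7)
        if not mat.any():
            mat[0, 0] = True
        inc = inc_from_bool(mat)
        curve = rarefaction(inc)
        for h in range(1, m + 1):
            assert curve.at(h).tau == pytest.approx(exhaustive_tau(inc, h))

    def test_monotone_and_concave(self, rng):
        mat = rng.random((20, 8)) < 0.35
        mat[:, 0] = True
        curve = rarefaction(inc_from_bool(mat))
        taus = [p.tau for p in curve.points]
        diffs = np.diff(taus)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_ci_bounds_bracket_mean(self, rng):
        mat = rng.random((15, 7)) < 0.3
        mat[:, 0] = True
        for p in rarefaction(inc_from_bool(mat)).points:
            assert p.lo84 <= p.tau <= p.hi84
            assert p.lo84 >= 0.0

    def test_variance_tracks_event_bootstrap(self):
        """Unconditional variance within a factor 2 of a resampling oracle in
        the homogeneous-detectability regime the estimator assumes."""
        rng = np.random.default_rng(3)
        K, m, p = 40, 12, 0.25
        mat = rng.random((K, m)) < p
        inc = inc_from_bool(mat)
        curve = rarefaction(inc)
        rngb = np.random.default_rng(9)
        full = inc.table.to_numpy()
        for h in (3, 6):
            boots = []
            for _ in range(400):
                cols = rngb.integers(0, m, size=m)
                sub = inc_from_bool(full[:, cols])
                boots.append(rarefaction(sub, s_est=chao2_point(inc)).at(h).tau)
            bv = np.var(boots, ddof=1)
            assert 0.5 < curve.at(h).var / bv < 2.0

    def test_h_beyond_m_rejected(self):
        inc = inc_from_bool([[1, 0], [1, 1]])
        with pytest.raises(KeyError):
            rarefaction(inc).at(3)


class TestChao2:
    def test_no_uniques_estimate_is_sobs(self):
        inc = inc_from_bool([[1, 1, 0], [0, 1, 1], [1, 1, 1]])
        est = chao2(inc)
        assert est.point == pytest.approx(3.0)
        assert (est.lo84, est.hi84) == (3.0, 3.0)

    def test_hand_formula_classic_branch(self):
        # S_obs=5, Q1=2, Q2=1, m=4 -> 5 + (3/4) * 4/2 = 6.5
        mat = np.zeros((5, 4), dtype=bool)
        mat[0, 0] = True                 # Q1
        mat[1, 1] = True                 # Q1
        mat[2, :2] = True                # Q2
        mat[3, :3] = True
        mat[4, :] = True
        inc = inc_from_bool(mat)
        assert (inc.q1, inc.q2) == (2, 1)
        assert chao2(inc).point == pytest.approx(6.5)

    def test_hand_formula_bias_corrected_branch(self):
        # S_obs=4, Q1=3, Q2=0, m=5 -> 4 + (4/5) * 3*2/2 = 6.4
        mat = np.zeros((4, 5), dtype=bool)
        mat[0, 0] = True
        mat[1, 1] = True
        mat[2, 2] = True
        mat[3, :3] = True
        inc = inc_from_bool(mat)
        assert (inc.q1, inc.q2) == (3, 0)
        assert chao2(inc).point == pytest.approx(6.4)

    def test_estimate_at_least_sobs(self, rng):
        for _ in range(20):
            mat = rng.random((rng.integers(5, 25), rng.integers(3, 10))) < 0.3
            if not mat.any():
                continue
            inc = inc_from_bool(mat)
            assert chao2(inc).point >= inc.s_obs - 1e-12

    def test_empty_event_changes_only_m(self):
        mat = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=bool)
        inc = inc_from_bool(mat)
        padded = inc_from_bool(np.hstack([mat, np.zeros((3, 1), dtype=bool)]))
        assert (padded.s_obs, padded.q1, padded.q2) == (inc.s_obs, inc.q1, inc.q2)
        assert padded.m == inc.m + 1
        # k = (m-1)/m grows, so the estimate moves accordingly
        k3, k4 = 2 / 3, 3 / 4
        assert chao2(padded).point - padded.s_obs == pytest.approx(
            (chao2(inc).point - inc.s_obs) * k4 / k3)

    def test_variance_within_25pct_of_bootstrap(self):
        rng = np.random.default_rng(42)
        K, m = 60, 20
        p = rng.uniform(0.05, 0.6, size=K)
        inc = inc_from_bool(rng.random((K, m)) < p[:, None])
        est = chao2(inc)
        boot = bootstrap_chao2(inc, 500, np.random.default_rng(7))
        bv = boot.var(ddof=1)
        assert abs(est.var - bv) / bv < 0.25

    def test_ci_coverage_near_nominal(self):
        """84% CI covers the true richness in ~84% +/- 10 points of
        replicates under homogeneous detectability."""
        rng = np.random.default_rng(1)
        K, m, p = 40, 12, 0.15
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            mat = rng.random((K, m)) < p
            inc = inc_from_bool(mat)
            e = chao2(inc)
            covered += e.lo84 <= K <= e.hi84
        assert 0.74 <= covered / n_rep <= 0.94

    def test_m_below_2_rejected(self):
        with pytest.raises(ValueError):
            chao2(inc_from_bool([[1], [1]]))


class TestCIOverlap:
    def test_identical_not_significant(self):
        a = RichnessEstimate("chao2", 10, 1.0, 8.0, 12.0)
        assert ci_overlap(a, a) == "not_significant"

    def test_disjoint_significant(self):
        a = RichnessEstimate("chao2", 11, 1.0, 10.0, 12.0)
        b = RichnessEstimate("chao2", 14, 1.0, 13.0, 15.0)
        assert ci_overlap(a, b) == "significant"
        assert ci_overlap(b, a) == "significant"

    def test_mismatched_levels_rejected(self):
        a = RichnessEstimate("chao2", 11, 1.0, 10.0, 12.0, z=Z_84)
        b = RichnessEstimate("chao2", 14, 1.0, 13.0, 15.0, z=1.96)
        with pytest.raises(ValueError, match="confidence"):
            ci_overlap(a, b)

    def test_curves_compared_at_min_effort(self, rng):
        mat_a = rng.random((30, 8)) < 0.5
        mat_b = rng.random((10, 6)) < 0.5
        mat_a[:, 0] = True
        mat_b[:, 0] = True
        ca = rarefaction(inc_from_bool(mat_a))
        cb = rarefaction(inc_from_bool(mat_b))
        verdict = ci_overlap(ca, cb)   # h defaults to min(8, 6)
        assert verdict in ("significant", "not_significant")
        with pytest.raises(ValueError, match="exceeds"):
            ci_overlap(ca, cb, h=7)

    def test_splitting_error_separates_curves(self):
        """Strong field splitting inflates the field curve beyond the barcode
        curve's 84% band at the common effort."""
        rng = np.random.default_rng(8)
        events = [f"E{j}" for j in range(10)]
        records = []
        k = 0
        for sp in range(12):
            for ev in events:
                for dup in range(2):
                    k += 1
                    # every species split into 4 pseudo-labels in the field
                    records.append(survey(
                        f"s{k}", morpho=f"Xeno sp{sp}l{rng.integers(0, 4)}",
                        event=ev))
        by_field = build_incidence(records, lambda r: r.field_morphospecies)
        by_truth = build_incidence(
            records, lambda r: r.field_morphospecies.split("l")[0])
        verdict = ci_overlap(rarefaction(by_field), rarefaction(by_truth))
        assert verdict == "significant"
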