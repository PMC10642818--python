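import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapstruct.differentiation import (
    LocusData,
    RegionPartition,
    analyze_partition,
    diversity_components,
    gst_nst,
    jackknife_loci,
    permutation_test_region,
    phylogeo_signal_test,
    pooled_gst_nst,
)
from hapstruct.distances import AlleleDistanceMatrix
from hapstruct.errors import InputError, InsufficientSampleError

from _oracles import brute_components, brute_gst_nst
from conftest import make_locus


class TestDiversityComponents:
    def test_worked_example(self):
        # A = {h1:2, h2:2}, B = {h1:4}, delta = 0.1
        v_s, v_t = diversity_components(
            np.array([[0.5, 0.5], [1.0, 0.0]]), [4, 4],
            np.array([[0, 0.1], [0.1, 0]]))
        assert v_s == pytest.approx(0.033333, abs=1e-6)
        assert v_t == pytest.approx(0.041667, abs=1e-6)

    def test_zero_delta_gives_zero(self):
        v_s, v_t = diversity_components(
            np.array([[0.5, 0.5], [0.2, 0.8]]), [5, 5], np.zeros((2, 2)))
        assert v_s == 0.0 and v_t == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            diversity_components(np.array([[1.0], [1.0]]), [1, 5], np.zeros((1, 1)))

    def test_identical_frequencies_give_small_gst(self):
        # same frequency vector in both regions: differentiation ~ 0
        counts = [[10, 10], [10, 10]]
        gst, _ = brute_gst_nst(counts, [[0, 1], [1, 0]])
        assert abs(gst) < 0.05


class TestGstNst:
    def test_complete_fixation(self):
        locus, part = make_locus([[5, 0], [0, 5]], [[0, 0.3], [0.3, 0]])
        st_ = gst_nst(locus.haps, locus.delta, part)
        assert st_.gst_raw == pytest.approx(1.0, abs=1e-12)
        assert st_.nst_raw == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_gst_equals_nst_point_two(self, worked_locus):
        locus, part = worked_locus
        st_ = gst_nst(locus.haps, locus.delta, part)
        assert st_.gst_raw == pytest.approx(0.2, abs=1e-12)
        assert st_.nst_raw == pytest.approx(0.2, abs=1e-12)

    def test_monomorphic_is_na(self):
        locus, part = make_locus([[4], [4]], [[0.0]])
        st_ = gst_nst(locus.haps, locus.delta, part)
        assert st_.gst_raw is None and st_.nst_raw is None

    def test_negative_raw_clamped_for_display(self):
        locus, part = make_locus([[3, 3], [3, 3]], [[0, 1], [1, 0]])
        st_ = gst_nst(locus.haps, locus.delta, part)
        assert st_.gst_raw < 0 < 1e-9 + st_.gst  # display clamps at 0

    def test_within_never_exceeds_total_for_positive_estimates(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 4, size=(2, 3))
            if counts.sum(1).min() < 2:
                continue
            locus, part = make_locus(counts, 1 - np.eye(3))
            st_ = gst_nst(locus.haps, locus.delta, part)
            if st_.gst_raw is not None and st_.gst_raw >= 0:
                assert st_.hS <= st_.hT + 1e-12

    def test_exhaustive_grid_matches_bruteforce(self):
        """Estimator oracle on every small two-region dataset (H = 2, 3)."""
        rng = np.random.default_rng(42)
        checked = 0
        for H in (2, 3):
            delta = rng.uniform(0.01, 0.5, size=(H, H))
            delta = (delta + delta.T) / 2
            np.fill_diagonal(delta, 0.0)
            cells = itertools.product(range(4), repeat=H)
            for ca, cb in itertools.product(list(cells), repeat=2):
                if sum(ca) < 2 or sum(cb) < 2:
                    continue
                counts = [list(ca), list(cb)]
                ref_g, ref_n = brute_gst_nst(counts, delta.tolist())
                locus, part = make_locus(counts, delta)
                st_ = gst_nst(locus.haps, locus.delta, part)
                for ref, got in ((ref_g, st_.gst_raw), (ref_n, st_.nst_raw)):
                    if ref is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(ref, abs=1e-12)
                checked += 1
        assert checked > 3000

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_random_five_haplotype_datasets_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(2, 6))
        counts = rng.integers(0, 4, size=(2, H))
        if counts.sum(axis=1).min() < 2:
            return
        delta = rng.uniform(0, 1, size=(H, H))
        delta = (delta + delta.T) / 2
        np.fill_diagonal(delta, 0)
        ref_g, ref_n = brute_gst_nst(counts.tolist(), delta.tolist())
        locus, part = make_locus(counts, delta)
        st_ = gst_nst(locus.haps, locus.delta, part)
        if ref_g is not None:
            assert st_.gst_raw == pytest.approx(ref_g, abs=1e-12)
        if ref_n is not None:
            assert st_.nst_raw == pytest.approx(ref_n, abs=1e-12)

    def test_constant_delta_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            H = int(rng.integers(2, 5))
            counts = rng.integers(0, 5, size=(2, H))
            if counts.sum(axis=1).min() < 2:
                continue
            c = float(rng.uniform(0.05, 2.0))
            locus, part = make_locus(counts, c * (1 - np.eye(H)))
            st_ = gst_nst(locus.haps, locus.delta, part)
            if st_.gst_raw is not None:
                assert st_.nst_raw == pytest.approx(st_.gst_raw, abs=1e-12)


class TestPooling:
    def test_pooled_equals_single_locus(self, worked_locus):
        locus, part = worked_locus
        gst, nst = pooled_gst_nst([locus], part)
        assert gst == pytest.approx(0.2, abs=1e-12)
        assert nst == pytest.approx(0.2, abs=1e-12)

    def test_ratio_of_sums_over_loci(self):
        la, part = make_locus([[2, 2], [4, 0]], [[0, 0.1], [0.1, 0]], "l1")
        lb, _ = make_locus([[5, 0], [0, 5]], [[0, 0.3], [0.3, 0]], "l2")
        # independent hand-pooling from per-locus components
        sa = gst_nst(la.haps, la.delta, part)
        partb = RegionPartition({i: ("north" if i.startswith("north") else "south")
                                 for i in lb.haps.ids})
        sb = gst_nst(lb.haps, lb.delta, partb)
        # merge the two label maps (disjoint ids), pool
        merged = RegionPartition({**part.labels, **partb.labels})
        gst, _ = pooled_gst_nst([la, lb], merged)
        expected = ((sa.hT - sa.hS) + (sb.hT - sb.hS)) / (sa.hT + sb.hT)
        assert gst == pytest.approx(expected, abs=1e-12)


class TestPermutationTests:
    def test_complete_fixation_is_extreme(self):
        locus, part = make_locus([[10, 0], [0, 10]], [[0, 0.3], [0.3, 0]])
        p_gst, p_nst = permutation_test_region([locus], part, n_perm=1000, seed=0)
        assert p_gst <= 0.01 and p_nst <= 0.01

    def test_monomorphic_gives_none(self):
        locus, part = make_locus([[4], [4]], [[0.0]])
        p_gst, p_nst = permutation_test_region([locus], part, n_perm=100, seed=0)
        assert p_gst is None and p_nst is None

    def test_deterministic_under_seed(self, worked_locus):
        locus, part = worked_locus
        a = permutation_test_region([locus], part, n_perm=300, seed=11)
        b = permutation_test_region([locus], part, n_perm=300, seed=11)
        assert a == b

    def test_add_one_estimator_never_zero(self, worked_locus):
        locus, part = worked_locus
        p_gst, p_nst = permutation_test_region([locus], part, n_perm=50, seed=1)
        assert 0 < p_gst <= 1 and 0 < p_nst <= 1


class TestPhylogeoSignal:
    def test_constant_delta_gives_p_one(self):
        locus, part = make_locus([[3, 2, 1], [1, 2, 3]], 0.2 * (1 - np.eye(3)))
        assert phylogeo_signal_test([locus], part, n_perm=200, seed=0) == 1.0

    def test_two_haplotypes_give_p_one(self):
        locus, part = make_locus([[4, 1], [1, 4]], [[0, 0.3], [0.3, 0]])
        assert phylogeo_signal_test([locus], part, n_perm=200, seed=0) == 1.0

    def test_matches_bruteforce_matrix_permutation(self):
        """Relabeling haplotypes == jointly permuting rows/cols of delta."""
        rng = np.random.default_rng(5)
        delta = np.array([[0, 0.5, 0.4, 0.05],
                          [0.5, 0, 0.1, 0.45],
                          [0.4, 0.1, 0, 0.35],
                          [0.05, 0.45, 0.35, 0]])
        counts = [[6, 5, 1, 0], [1, 0, 5, 6]]
        locus, part = make_locus(counts, delta)
        obs = gst_nst(locus.haps, locus.delta, part).nst_raw
        n_perm = 400
        count = 0
        for r in range(n_perm):
            perm = rng.permutation(4)
            dp = AlleleDistanceMatrix(delta[np.ix_(perm, perm)])
            nst_p = gst_nst(locus.haps, dp, part).nst_raw
            if nst_p >= obs - 1e-12:
                count += 1
        brute_p = (1 + count) / (1 + n_perm)
        fast_p = phylogeo_signal_test([locus], part, n_perm=2000, seed=9)
        assert fast_p == pytest.approx(brute_p, abs=0.05)

    def test_monomorphic_gives_none(self):
        locus, part = make_locus([[4], [4]], [[0.0]])
        assert phylogeo_signal_test([locus], part, n_perm=100, seed=0) is None


class TestJackknife:
    def test_three_locus_formula(self):
        # theta(-l) = 0.1, 0.2, 0.3
        vals = iter([0.1, 0.2, 0.3])
        res = jackknife_loci([1, 2, 3], lambda rest: next(vals))
        assert res.mean == pytest.approx(0.2)
        assert res.se == pytest.approx(0.11547, abs=1e-5)
        assert res.halfwidth == pytest.approx(0.22632, abs=1e-4)

    def test_equal_estimates_zero_halfwidth(self):
        res = jackknife_loci([1, 2, 3], lambda rest: 0.42)
        assert res.halfwidth == 0.0

    def test_single_locus_is_na(self):
        assert jackknife_loci([1], lambda rest: 0.1) is None


class TestAnalyzePartition:
    def test_full_multilocus_analysis(self):
        la, _ = make_locus([[4, 2], [1, 5]], [[0, 0.1], [0.1, 0]], "l1")
        lb, _ = make_locus([[5, 0], [0, 5]], [[0, 0.3], [0.3, 0]], "l2")
        part = RegionPartition({**{i: "north" for i in la.haps.ids if i.startswith("north")},
                                **{i: "south" for i in la.haps.ids if i.startswith("south")},
                                **{i: "north" for i in lb.haps.ids if i.startswith("north")},
                                **{i: "south" for i in lb.haps.ids if i.startswith("south")}})
        res = analyze_partition([la, lb], part, n_perm=200, seed=1)
        assert len(res.per_locus) == 2
        assert res.gst_jack is not None and res.nst_jack is not None
        assert 0 < res.p_gst <= 1 and 0 < res.p_nst_gt_gst <= 1

    def test_requires_loci(self):
        part = RegionPartition({"a": "north", "b": "south"})
        with pytest.raises(InputError):
            analyze_partition([], part, n_perm=10, seed=0)
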