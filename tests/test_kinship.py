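import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapstruct.distances import HaplotypeAssignment
from hapstruct.errors import InputError
from hapstruct.kinship import (
    KinshipMatrix,
    compare_scales,
    distance_matrix_km,
    great_circle_km,
    ibd_regression,
    ibd_slope_jackknife,
    loiselle_kinship,
)

from _oracles import brute_loiselle


def _haps(hap_indices, locus="L"):
    H = max(hap_indices) + 1
    seqs = ["A" * (i + 1) + "C" * (H - i) for i in range(H)]
    ids = [f"i{k}" for k in range(len(hap_indices))]
    return HaplotypeAssignment(locus, seqs, dict(zip(ids, hap_indices))), ids


class TestLoiselleKinship:
    def test_worked_four_individual_example(self):
        # haplotypes (h1, h1, h2, h3): F(1,2) = 0.375/0.625 + 1/3
        haps, ids = _haps([0, 0, 1, 2])
        kin = loiselle_kinship([haps], ids)
        assert kin.fij[0, 1] == pytest.approx(0.375 / 0.625 + 1 / 3, abs=1e-12)
        assert kin.fij[0, 1] == pytest.approx(0.93333, abs=1e-5)

    def test_mean_over_pairs_is_exactly_zero(self):
        haps, ids = _haps([0, 0, 1, 2])
        kin = loiselle_kinship([haps], ids)
        iu = np.triu_indices(4, k=1)
        assert kin.fij[iu].mean() == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_mean_zero_identity_holds_for_any_single_locus(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        idx = rng.integers(0, rng.integers(2, 6), size=n).tolist()
        if len(set(idx)) < 2:
            return
        haps, ids = _haps(idx)
        kin = loiselle_kinship([haps], ids)
        iu = np.triu_indices(n, k=1)
        assert kin.fij[iu].mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_multilocus(self):
        rng = np.random.default_rng(1)
        idx1 = rng.integers(0, 3, size=8).tolist()
        idx2 = rng.integers(0, 4, size=8).tolist()
        h1, ids = _haps(idx1, "l1")
        h2, _ = _haps(idx2, "l2")
        kin = loiselle_kinship([h1, h2], ids)
        ref = brute_loiselle([idx1, idx2], [3, 4])
        for i in range(8):
            for j in range(8):
                if i != j and ref[i][j] is not None:
                    assert kin.fij[i, j] == pytest.approx(ref[i][j], abs=1e-12)

    def test_identical_pair_ranks_highest(self):
        haps, ids = _haps([0, 0, 1, 2, 3])
        kin = loiselle_kinship([haps], ids)
        match = kin.fij[0, 1]
        others = [kin.fij[i, j] for i in range(5) for j in range(i + 1, 5)
                  if (i, j) != (0, 1)]
        assert all(match >= o for o in others)

    def test_all_monomorphic_gives_nan(self):
        haps, ids = _haps([0, 0, 0])
        kin = loiselle_kinship([haps], ids)
        assert np.isnan(kin.fij[0, 1])

    def test_symmetry(self):
        haps, ids = _haps([0, 1, 2, 0, 1])
        f = loiselle_kinship([haps], ids).fij
        assert np.allclose(f[~np.isnan(f)], f.T[~np.isnan(f.T)])


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km(45.0, 5.0, 45.0, 5.0) == 0.0

    def test_antipodal(self):
        assert great_circle_km(0, 0, 0, 180) == pytest.approx(
            math.pi * 6371.0, abs=0.01)

    def test_one_degree_longitude_at_equator(self):
        assert great_circle_km(0, 0, 0, 1) == pytest.approx(111.195, abs=0.001)

    def test_symmetry(self):
        assert great_circle_km(41, 3, 48, 5) == great_circle_km(48, 5, 41, 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            great_circle_km(91, 0, 0, 0)

    def test_missing_coordinates_give_nan(self):
        d = distance_matrix_km(["a", "b"], {"a": (45.0, 5.0)})
        assert np.isnan(d[0, 1]) and d[0, 0] == 0.0


def _ibd_inputs(n=12, noise=0.0, seed=0):
    """Noise-free (or noisy) strictly decreasing kinship with distance."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    coords = {ids[k]: (45.0, 0.2 * k) for k in range(n)}
    d = distance_matrix_km(ids, coords)
    fij = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                fij[i, j] = 0.5 - 0.001 * d[i, j] + noise * rng.normal()
                fij[j, i] = fij[i, j]
    return KinshipMatrix(ids, fij), d


class TestIBDRegression:
    def test_constant_kinship_zero_slope(self):
        kin, d = _ibd_inputs()
        kin.fij[np.isfinite(kin.fij)] = 0.25
        res = ibd_regression(kin, d, n_perm=50, seed=0)
        assert res.slope == pytest.approx(0.0, abs=1e-15)
        assert res.r2 == pytest.approx(0.0, abs=1e-15)

    def test_noise_free_decay_is_significant(self):
        kin, d = _ibd_inputs()
        res = ibd_regression(kin, d, n_perm=1000, seed=0)
        assert res.slope == pytest.approx(-0.001, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.mantel_p <= 0.05

    def test_relabeling_invariance(self):
        kin, d = _ibd_inputs(noise=0.05, seed=3)
        res = ibd_regression(kin, d, n_perm=200, seed=7)
        perm = np.random.default_rng(0).permutation(kin.n)
        kin2 = KinshipMatrix([kin.ids[i] for i in perm],
                             kin.fij[np.ix_(perm, perm)])
        d2 = d[np.ix_(perm, perm)]
        res2 = ibd_regression(kin2, d2, n_perm=200, seed=7)
        assert res2.slope == pytest.approx(res.slope, abs=1e-12)
        assert res2.r2 == pytest.approx(res.r2, abs=1e-12)

    def test_log_scale_excludes_zero_distances(self):
        kin, d = _ibd_inputs()
        d[0, 1] = d[1, 0] = 0.0
        res = ibd_regression(kin, d, scale="log", n_perm=10, seed=0)
        n = kin.n
        assert res.n_pairs == n * (n - 1) // 2 - 1

    def test_all_distances_equal_gives_none(self):
        kin, _ = _ibd_inputs(n=4)
        d = np.full((4, 4), 100.0)
        np.fill_diagonal(d, 0.0)
        # place all individuals at one point: pair distances all equal
        d[:] = 7.0
        np.fill_diagonal(d, 0.0)
        res = ibd_regression(kin, d, n_perm=10, seed=0)
        assert res.slope is None

    def test_fewer_than_three_placed_individuals(self):
        kin, d = _ibd_inputs(n=5)
        d[:] = np.nan
        res = ibd_regression(kin, d, n_perm=10, seed=0)
        assert res.slope is None and res.n_pairs == 0


class TestSlopeJackknife:
    def test_two_loci_give_jackknife(self):
        rng = np.random.default_rng(0)
        n = 10
        idx1 = rng.integers(0, 3, size=n).tolist()
        idx2 = rng.integers(0, 3, size=n).tolist()
        h1, ids = _haps(idx1, "l1")
        h2, _ = _haps(idx2, "l2")
        coords = {ids[k]: (45.0, 0.3 * k) for k in range(n)}
        d = distance_matrix_km(ids, coords)
        res = ibd_slope_jackknife([h1, h2], ids, d)
        assert res is not None and res.halfwidth >= 0

    def test_single_locus_is_na(self):
        h1, ids = _haps([0, 1, 0, 1], "l1")
        d = distance_matrix_km(ids, {i: (45.0, k * 0.1)
                                     for k, i in enumerate(ids)})
        assert ibd_slope_jackknife([h1], ids, d) is None


class TestCompareScales:
    def test_identical_lists(self):
        res = compare_scales([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.t == 0.0 and res.p_two_sided == 1.0

    def test_hand_computed_toy(self):
        # d = (0.04, 0.00): mean 0.02, sd 0.028284 -> t = 1, df = 1, p = 0.5
        res = compare_scales([0.02, 0.01], [0.06, 0.01])
        assert res.t == pytest.approx(1.0, abs=1e-12)
        assert res.df == 1
        assert res.p_two_sided == pytest.approx(0.5, abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(InputError):
            compare_scales([0.1], [0.2])
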