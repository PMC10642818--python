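"""Pairwise kinship, great-circle distances, and isolation-by-distance tests.

Kinship between haploid individuals is the Loiselle-type estimator: the
correlation of allelic state relative to the sample allele (haplotype)
frequencies, with a small-sample correction term that makes the mean over
all distinct pairs exactly zero for a fully scored single-locus dataset.
Kinship is regressed on pairwise great-circle distance (optionally
log-transformed); the slope's significance comes from a Mantel permutation
of the individuals' coordinate assignments, one-tailed against the
isolation-by-distance expectation of a negative slope.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .distances import HaplotypeAssignment
from .errors import InputError
from .differentiation import jackknife_loci, JackknifeResult

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class KinshipMatrix:
    """Pairwise Fij over an ordered list of individuals (diagonal NaN)."""

    ids: list[str]
    fij: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)


def loiselle_kinship(
    haps_by_locus: Sequence[HaplotypeAssignment], ids: Sequence[str]
) -> KinshipMatrix:
    """Multilocus kinship Fij for haploid individuals.

    Per locus l with allele indicator x_ia and sample frequencies p_a over
    the n_l scored individuals:

        num_l(i,j) = Σ_a (x_ia - p_a)(x_ja - p_a) + Σ_a p_a(1-p_a)/(n_l - 1)
        den_l      = Σ_a p_a(1-p_a)

    and Fij = Σ_l num_l / Σ_l den_l (ratio of sums; loci where either
    individual is unscored are left out of both sums for that pair).
    Monomorphic loci (den_l = 0) are skipped with a warning; if every locus
    is monomorphic the matrix is all-NaN.
    """
    if not haps_by_locus:
        raise InputError("need at least one locus")
    ids = list(ids)
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    num_sum = np.zeros((n, n))
    den_sum = np.zeros((n, n))
    any_locus = False
    for haps in haps_by_locus:
        scored = [i for i in haps.ids if i in pos]
        n_l = len(scored)
        if n_l < 2:
            log.warning("locus %s: fewer than 2 scored individuals; skipped",
                        haps.locus_name)
            continue
        h = haps.n_haplotypes
        z = np.zeros((n_l, h))
        z[np.arange(n_l), haps.indices(scored)] = 1.0
        p = z.mean(axis=0)
        den = float(np.sum(p * (1.0 - p)))
        if den <= 0.0:
            log.warning("locus %s is monomorphic; skipped from kinship",
                        haps.locus_name)
            continue
        any_locus = True
        c = (z - p) @ (z - p).T + den / (n_l - 1)
        idx = np.array([pos[i] for i in scored], dtype=np.intp)
        num_sum[np.ix_(idx, idx)] += c
        den_sum[np.ix_(idx, idx)] += den
    fij = np.full((n, n), np.nan)
    if any_locus:
        mask = den_sum > 0
        fij[mask] = num_sum[mask] / den_sum[mask]
    np.fill_diagonal(fij, np.nan)
    return KinshipMatrix(ids=ids, fij=fij)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km (Earth radius 6371.0 km)."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise InputError(f"coordinates out of range: ({lat}, {lon})")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def distance_matrix_km(
    ids: Sequence[str], coords: dict[str, tuple[float, float]]
) -> np.ndarray:
    """Pairwise great-circle distances; NaN where either id lacks coordinates."""
    n = len(ids)
    d = np.full((n, n), np.nan)
    for i in range(n):
        ci = coords.get(ids[i])
        if ci is None:
            continue
        d[i, i] = 0.0
        for j in range(i + 1, n):
            cj = coords.get(ids[j])
            if cj is None:
                continue
            d[i, j] = d[j, i] = great_circle_km(*ci, *cj)
    return d


@dataclass
class IBDResult:
    """OLS fit of kinship on (possibly log) distance, with Mantel inference."""

    slope: Optional[float]
    intercept: Optional[float]
    r2: Optional[float]
    mantel_p: Optional[float]
    n_pairs: int
    distance_scale: str  # "linear" | "log"
    slope_jack: Optional[JackknifeResult] = None


def _pair_vectors(fij: np.ndarray, dists: np.ndarray, scale: str):
    n = fij.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    f = fij[iu, ju]
    d = dists[iu, ju]
    ok = np.isfinite(f) & np.isfinite(d)
    if scale == "log":
        nonpos = ok & (d <= 0)
        if nonpos.any():
            log.warning("%d zero-distance pairs excluded under log scale",
                        int(nonpos.sum()))
        ok &= d > 0
    return iu[ok], ju[ok], f[ok], (np.log(d[ok]) if scale == "log" else d[ok])


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 2:
        return None, None, None
    vx = x - x.mean()
    sxx = float(vx @ vx)
    if sxx <= 0.0:
        return None, None, None
    slope = float(vx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if syy == 0.0 else slope * slope * sxx / syy
    return slope, intercept, r2


def ibd_regression(
    kin: KinshipMatrix,
    dists: np.ndarray,
    scale: str = "linear",
    n_perm: int = 1000,
    seed=None,
    alternative: str = "less",
) -> IBDResult:
    """Regress pairwise kinship on geographic distance, Mantel-test the slope.

    The Mantel permutation relabels individuals' coordinates (rows and
    columns of the distance matrix jointly, one permutation per replicate)
    and recomputes the slope; the default alternative "less" is one-tailed
    for the negative slope expected under isolation by distance
    ("greater" and "two-sided" are available).  All distances equal (or
    fewer than 3 placed individuals) yields a None slope.
    """
    if scale not in ("linear", "log"):
        raise InputError("scale must be 'linear' or 'log'")
    if alternative not in ("less", "greater", "two-sided"):
        raise InputError(f"unknown alternative {alternative!r}")
    fij = kin.fij
    if dists.shape != fij.shape:
        raise InputError("distance matrix shape does not match kinship")
    n = fij.shape[0]
    placed = np.isfinite(np.diagonal(dists))
    if placed.sum() < 3:
        return IBDResult(None, None, None, None, 0, scale)
    iu, ju, f, x = _pair_vectors(fij, dists, scale)
    n_pairs = len(f)
    slope, intercept, r2 = _ols(x, f)
    if slope is None:
        return IBDResult(None, None, r2, None, n_pairs, scale)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n)
        dp = dists[np.ix_(perm, perm)]
        _, _, fp, xp = _pair_vectors(fij, dp, scale)
        s, _, _ = _ols(xp, fp)
        slopes[r] = np.nan if s is None else s
    if alternative == "less":
        exceed = int(np.sum(slopes <= slope + 1e-12))
    elif alternative == "greater":
        exceed = int(np.sum(slopes >= slope - 1e-12))
    else:
        exceed = int(np.sum(np.abs(slopes) >= abs(slope) - 1e-12))
    mantel_p = (1 + exceed) / (1 + n_perm)
    return IBDResult(slope, intercept, r2, mantel_p, n_pairs, scale)


def ibd_slope_jackknife(
    haps_by_locus: Sequence[HaplotypeAssignment],
    ids: Sequence[str],
    dists: np.ndarray,
    scale: str = "linear",
) -> Optional[JackknifeResult]:
    """Delete-one-locus jackknife of the IBD slope (None for single-locus data)."""

    def stat(rest):
        kin = loiselle_kinship(rest, ids)
        _, _, f, x = _pair_vectors(kin.fij, dists, scale)
        if len(f) < 3:
            return None
        s, _, _ = _ols(x, f)
        return s

    return jackknife_loci(list(haps_by_locus), stat)


@dataclass
class ScaleComparison:
    """Paired t-test of log- vs linear-distance regression fit (r²)."""

    t: float
    df: int
    p_two_sided: float
    mean_linear: float
    sd_linear: float
    mean_log: float
    sd_log: float
    n: int


def compare_scales(
    r2_linear: Sequence[float], r2_log: Sequence[float]
) -> ScaleComparison:
    """Does log-transforming distance improve r²?  Paired t over species.

    Differences are r²(log) - r²(linear); zero variance of the differences
    yields t = 0, p = 1 with a warning.
    """
    a = np.asarray(r2_linear, dtype=float)
    b = np.asarray(r2_log, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired lists must have equal length")
    n = len(a)
    if n < 2:
        raise InputError("need at least 2 pairs for a paired t-test")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero variance of paired differences; p set to 1")
        t, p = 0.0, 1.0
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return ScaleComparison(
        t=t, df=n - 1, p_two_sided=p,
        mean_linear=float(a.mean()), sd_linear=float(a.std(ddof=1)),
        mean_log=float(b.mean()), sd_log=float(b.std(ddof=1)), n=n,
    )
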