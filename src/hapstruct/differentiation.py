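"""Gst/Nst differentiation between regions, permutation inference, jackknife.

The statistics follow the ordered/unordered-allele framework of Pons & Petit
(the SPAGeDi estimators): with per-region haplotype sample frequencies x_ik
(region k of allele sample size n_k) and an inter-allele distance matrix δ,

    v̂_k = n_k/(n_k-1) · Σ_{i,j} x_ik x_jk δij          (within-region)
    v̂S  = (1/K) Σ_k v̂_k                                (unweighted average)
    v̂T  = Σ_{i,j} x̄_i x̄_j δij + v̂S/(K·ñ),  x̄ = mean over regions,
                                              ñ = harmonic mean of n_k

and the differentiation statistic is (v̂T - v̂S)/v̂T.  With δ the K2P
inter-haplotype distance this is Nst; with the mismatch indicator
(δij = 1 for i≠j) the v's specialize to the gene-diversity components
hS/hT and the statistic is Gst.  Nst exceeding Gst indicates
phylogeographic signal: alleles co-occurring within a region are, on
average, phylogenetically closer than alleles from different regions.

Inference is by permutation: region labels permuted over individuals for the
null of no differentiation, and the allele distance matrix permuted by
random relabeling of haplotypes for the null of no phylogeographic signal
(Gst is invariant under the latter).  Multilocus statistics pool loci by
ratio of sums, and a delete-one-locus jackknife supplies standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import SampleMetadata
from .distances import AlleleDistanceMatrix, HaplotypeAssignment, mismatch_matrix
from .errors import InputError, InsufficientSampleError

#: numerical tolerance for >=-ties in permutation counts
_TIE_EPS = 1e-12


@dataclass
class RegionPartition:
    """Map individual id -> region label; written for K >= 2 regions."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.regions = sorted(set(self.labels.values()))
        if len(self.regions) < 2:
            raise InputError("need at least two nonempty regions")

    @classmethod
    def from_metadata(cls, meta: SampleMetadata, ids=None) -> "RegionPartition":
        region = meta.region_of()
        ids = meta.ids if ids is None else ids
        labels = {i: region[i] for i in ids if not _isna(region.get(i))}
        return cls(labels)

    @property
    def K(self) -> int:
        return len(self.regions)

    def n_k(self, ids: Sequence[str]) -> np.ndarray:
        """Allele sample sizes per region among the given individuals."""
        counts = {r: 0 for r in self.regions}
        for i in ids:
            counts[self.labels[i]] += 1
        return np.array([counts[r] for r in self.regions], dtype=float)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def harmonic_mean(n_k: np.ndarray) -> float:
    n_k = np.asarray(n_k, dtype=float)
    return len(n_k) / np.sum(1.0 / n_k)


def diversity_components(
    freqs: np.ndarray, n_k: np.ndarray, delta: AlleleDistanceMatrix | np.ndarray
) -> tuple[float, float]:
    """Within-region and total diversity components (v̂S, v̂T).

    freqs is the (K, H) matrix of per-region haplotype sample frequencies,
    n_k the allele sample sizes.  Sums run over ordered haplotype pairs
    (each unordered pair counted twice), which with the zero diagonal makes
    v̂_k a plain quadratic form.  NaN entries of δ (saturated pairs recorded
    as NA) are excluded, i.e. contribute zero.
    """
    x = np.asarray(freqs, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(n_k):
        raise InputError("freqs must be (K, H) with one row per region")
    if not np.allclose(x.sum(axis=1), 1.0):
        raise InputError("per-region frequencies must sum to 1")
    if np.any(n_k < 2):
        raise InsufficientSampleError(f"all regions need n_k >= 2, got {n_k}")
    d = delta.delta if isinstance(delta, AlleleDistanceMatrix) else np.asarray(delta, float)
    d = np.nan_to_num(d, nan=0.0)
    K = len(n_k)
    v_k = n_k / (n_k - 1.0) * np.einsum("ki,ij,kj->k", x, d, x)
    v_s = float(np.mean(v_k))
    xbar = x.mean(axis=0)
    v_t = float(xbar @ d @ xbar + v_s / (K * harmonic_mean(n_k)))
    return v_s, v_t


@dataclass
class LocusStats:
    """Single-locus diversity components and differentiation statistics."""

    locus_name: str
    n_k: np.ndarray
    hS: float
    hT: float
    vS: float
    vT: float
    gst_raw: Optional[float]  # None when the locus is monomorphic (hT = 0)
    nst_raw: Optional[float]

    @property
    def gst(self) -> Optional[float]:
        """Display value, clamped at 0 (negative raw estimates print as 0)."""
        return None if self.gst_raw is None else max(0.0, self.gst_raw)

    @property
    def nst(self) -> Optional[float]:
        return None if self.nst_raw is None else max(0.0, self.nst_raw)


def _region_counts(
    haps: HaplotypeAssignment, part: RegionPartition
) -> tuple[np.ndarray, list[str]]:
    """(K, H) haplotype count matrix over the labelled individuals of the locus."""
    ids = [i for i in haps.ids if i in part.labels]
    if not ids:
        raise InputError(f"locus {haps.locus_name!r}: no individuals with region labels")
    counts = np.zeros((part.K, haps.n_haplotypes))
    ridx = {r: k for k, r in enumerate(part.regions)}
    for i in ids:
        counts[ridx[part.labels[i]], haps.assignment[i]] += 1
    return counts, ids


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den <= _TIE_EPS else num / den


def gst_nst(
    haps: HaplotypeAssignment, delta: AlleleDistanceMatrix, part: RegionPartition
) -> LocusStats:
    """Single-locus Gst and Nst between the partition's regions.

    Gst uses the mismatch indicator distance, Nst the supplied (K2P) δ.
    A monomorphic locus has hT = vT = 0 and both statistics are None.
    """
    if delta.size != haps.n_haplotypes:
        raise InputError("delta size does not match haplotype count")
    counts, ids = _region_counts(haps, part)
    n_k = counts.sum(axis=1)
    if np.any(n_k < 2):
        raise InsufficientSampleError(
            f"locus {haps.locus_name!r}: region sizes {n_k} (need >= 2 each)"
        )
    freqs = counts / n_k[:, None]
    h_s, h_t = diversity_components(freqs, n_k, mismatch_matrix(haps.n_haplotypes))
    v_s, v_t = diversity_components(freqs, n_k, delta)
    return LocusStats(
        locus_name=haps.locus_name, n_k=n_k, hS=h_s, hT=h_t, vS=v_s, vT=v_t,
        gst_raw=_ratio(h_t - h_s, h_t), nst_raw=_ratio(v_t - v_s, v_t),
    )


# ---------------------------------------------------------------------------
# multilocus machinery


@dataclass
class LocusData:
    """A locus ready for analysis: haplotypes plus inter-allele distances."""

    haps: HaplotypeAssignment
    delta: AlleleDistanceMatrix

    def __post_init__(self) -> None:
        if self.delta.size != self.haps.n_haplotypes:
            raise InputError(
                f"locus {self.haps.locus_name!r}: delta size {self.delta.size} "
                f"!= {self.haps.n_haplotypes} haplotypes"
            )


class _Prepared:
    """Indexing shared by the observed statistics and the permutation tests.

    Individuals are the union of labelled ids over loci, in first-appearance
    order; labels are encoded 0..K-1 in sorted region order.
    """

    def __init__(self, loci: Sequence[LocusData], part: RegionPartition):
        if not loci:
            raise InputError("no loci")
        self.part = part
        ids: list[str] = []
        seen = set()
        for ld in loci:
            for i in ld.haps.ids:
                if i in part.labels and i not in seen:
                    seen.add(i)
                    ids.append(i)
        if not ids:
            raise InputError("no labelled individuals in any locus")
        self.ids = ids
        ridx = {r: k for k, r in enumerate(part.regions)}
        self.y = np.array([ridx[part.labels[i]] for i in ids], dtype=np.intp)
        if np.bincount(self.y, minlength=part.K).min() < 2:
            raise InsufficientSampleError("each region needs >= 2 labelled individuals")
        pos_of = {i: p for p, i in enumerate(ids)}
        self.locus_pos: list[np.ndarray] = []   # positions into self.ids
        self.locus_Z: list[np.ndarray] = []     # (n_l, H) one-hot haplotype indicators
        self.locus_dv: list[np.ndarray] = []    # K2P delta, NaN -> 0
        self.locus_dh: list[np.ndarray] = []    # mismatch indicator delta
        self.names = [ld.haps.locus_name for ld in loci]
        for ld in loci:
            lids = [i for i in ld.haps.ids if i in part.labels]
            h = ld.haps.n_haplotypes
            z = np.zeros((len(lids), h))
            z[np.arange(len(lids)), ld.haps.indices(lids)] = 1.0
            self.locus_pos.append(np.array([pos_of[i] for i in lids], dtype=np.intp))
            self.locus_Z.append(z)
            self.locus_dv.append(np.nan_to_num(ld.delta.delta, nan=0.0))
            self.locus_dh.append(1.0 - np.eye(h))

    def pooled(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pooled Gst and Nst for each row of a (R, n) label matrix.

        Loci are combined by ratio of sums: Σ_l (v̂T - v̂S) / Σ_l v̂T.
        Rows where a region falls below 2 individuals at some locus, or where
        the pooled denominator vanishes, yield NaN.
        """
        labels = np.atleast_2d(labels)
        R = labels.shape[0]
        num_h = np.zeros(R)
        den_h = np.zeros(R)
        num_v = np.zeros(R)
        den_v = np.zeros(R)
        bad = np.zeros(R, dtype=bool)
        K = self.part.K
        for pos, z, dv, dh in zip(self.locus_pos, self.locus_Z,
                                  self.locus_dv, self.locus_dh):
            sub = labels[:, pos]
            counts = np.stack(
                [((sub == k).astype(float)) @ z for k in range(K)], axis=0
            )  # (K, R, H)
            n_k = counts.sum(axis=2)  # (K, R)
            bad |= (n_k < 2).any(axis=0)
            n_safe = np.maximum(n_k, 2.0)
            x = counts / n_safe[:, :, None]
            for d, num, den in ((dh, num_h, den_h), (dv, num_v, den_v)):
                quad = np.einsum("krh,hg,krg->kr", x, d, x)
                v_k = n_safe / (n_safe - 1.0) * quad  # (K, R)
                v_s = v_k.mean(axis=0)
                xbar = x.mean(axis=0)  # (R, H)
                ntilde = K / (1.0 / n_safe).sum(axis=0)
                v_t = np.einsum("rh,hg,rg->r", xbar, d, xbar) + v_s / (K * ntilde)
                num += v_t - v_s
                den += v_t
        with np.errstate(invalid="ignore", divide="ignore"):
            gst = np.where(den_h > _TIE_EPS, num_h / np.where(den_h > 0, den_h, 1), np.nan)
            nst = np.where(den_v > _TIE_EPS, num_v / np.where(den_v > 0, den_v, 1), np.nan)
        gst[bad] = np.nan
        nst[bad] = np.nan
        return gst, nst


def _as_loci(loci) -> list[LocusData]:
    if isinstance(loci, LocusData):
        return [loci]
    return [ld if isinstance(ld, LocusData) else LocusData(*ld) for ld in loci]


def pooled_gst_nst(
    loci, part: RegionPartition
) -> tuple[Optional[float], Optional[float]]:
    """Multilocus Gst and Nst (ratio of sums over loci); None when undefined."""
    prep = _Prepared(_as_loci(loci), part)
    gst, nst = prep.pooled(prep.y[None, :])
    to_opt = lambda a: None if np.isnan(a[0]) else float(a[0])
    return to_opt(gst), to_opt(nst)


def _add_one_p(perm_vals: np.ndarray, observed: float, n_perm: int) -> float:
    exceed = int(np.sum(perm_vals >= observed - _TIE_EPS))  # NaN compares False
    return (1 + exceed) / (1 + n_perm)


def permutation_test_region(
    loci, part: RegionPartition, n_perm: int = 1000, seed=None
) -> tuple[Optional[float], Optional[float]]:
    """One-tailed permutation p-values for pooled Gst and Nst.

    Region labels are permuted over individuals (region sizes preserved); for
    multilocus data one permutation per replicate is applied to all loci.
    p = (1 + #{replicates >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    prep = _Prepared(_as_loci(loci), part)
    gst_obs, nst_obs = prep.pooled(prep.y[None, :])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(prep.y, (n_perm, 1)), axis=1)
    gst_perm, nst_perm = prep.pooled(perms)
    p_gst = None if np.isnan(gst_obs[0]) else _add_one_p(gst_perm, gst_obs[0], n_perm)
    p_nst = None if np.isnan(nst_obs[0]) else _add_one_p(nst_perm, nst_obs[0], n_perm)
    return p_gst, p_nst


def phylogeo_signal_test(
    loci, part: RegionPartition, n_perm: int = 1000, seed=None
) -> Optional[float]:
    """p-value for phylogeographic signal (Nst > Gst).

    The null of no phylogenetic structure of allelic differentiation is
    simulated by randomly relabeling haplotypes, i.e. jointly permuting rows
    and columns of δ (Gst is invariant; Nst is recomputed).  Equivalently,
    the per-region frequency vectors are permuted against a fixed δ, which
    is how the computation is vectorized here.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    loci = _as_loci(loci)
    prep = _Prepared(loci, part)
    _, nst_obs = prep.pooled(prep.y[None, :])
    if np.isnan(nst_obs[0]):
        return None
    rng = np.random.default_rng(seed)
    K = prep.part.K
    num_v = np.zeros(n_perm)
    den_v = np.zeros(n_perm)
    for pos, z, dv in zip(prep.locus_pos, prep.locus_Z, prep.locus_dv):
        h = z.shape[1]
        sub = prep.y[pos]
        counts = np.stack([((sub == k).astype(float)) @ z for k in range(K)])
        n_k = counts.sum(axis=1)
        x = counts / n_k[:, None]  # (K, H) observed frequencies
        # random relabelings sigma: permuted frequencies y with y[sigma[i]] = x[i]
        sigma = rng.permuted(np.tile(np.arange(h), (n_perm, 1)), axis=1)
        rows = np.arange(n_perm)[:, None]
        xp = np.zeros((n_perm, K, h))
        for k in range(K):
            xp[rows, k, sigma] = x[k]
        quad = np.einsum("rkh,hg,rkg->rk", xp, dv, xp)
        v_k = n_k[None, :] / (n_k[None, :] - 1.0) * quad
        v_s = v_k.mean(axis=1)
        xbar = xp.mean(axis=1)
        v_t = np.einsum("rh,hg,rg->r", xbar, dv, xbar) + v_s / (K * harmonic_mean(n_k))
        num_v += v_t - v_s
        den_v += v_t
    with np.errstate(invalid="ignore", divide="ignore"):
        nst_perm = np.where(den_v > _TIE_EPS, num_v / np.where(den_v > 0, den_v, 1), np.nan)
    return _add_one_p(nst_perm, nst_obs[0], n_perm)


@dataclass
class JackknifeResult:
    mean: float
    se: float
    halfwidth: float  # 1.96 * SE, the Table-1 "mean ± 1.96 SD" convention
    leave_one_out: list[float] = field(default_factory=list, repr=False)


def jackknife_loci(
    per_locus_inputs: Sequence, statistic: Callable[[Sequence], Optional[float]]
) -> Optional[JackknifeResult]:
    """Delete-one-locus jackknife of a recomputable multilocus statistic.

    Returns None for single-locus data (the Table-1 "NA otherwise" rule).
    SE = sqrt(((L-1)/L) · Σ_l (θ(-l) - mean)²).
    """
    L = len(per_locus_inputs)
    if L < 2:
        return None
    thetas = []
    for l in range(L):
        rest = [x for j, x in enumerate(per_locus_inputs) if j != l]
        t = statistic(rest)
        if t is None:
            return None
        thetas.append(t)
    arr = np.asarray(thetas, dtype=float)
    mean = float(arr.mean())
    se = float(np.sqrt((L - 1) / L * np.sum((arr - mean) ** 2)))
    return JackknifeResult(mean=mean, se=se, halfwidth=1.96 * se, leave_one_out=thetas)


@dataclass
class DiffStats:
    """Per-locus and pooled differentiation statistics with inference."""

    per_locus: list[LocusStats]
    gst_raw: Optional[float]
    nst_raw: Optional[float]
    p_gst: Optional[float] = None
    p_nst: Optional[float] = None
    p_nst_gt_gst: Optional[float] = None
    gst_jack: Optional[JackknifeResult] = None
    nst_jack: Optional[JackknifeResult] = None

    @property
    def gst(self) -> Optional[float]:
        return None if self.gst_raw is None else max(0.0, self.gst_raw)

    @property
    def nst(self) -> Optional[float]:
        return None if self.nst_raw is None else max(0.0, self.nst_raw)


def analyze_partition(
    loci, part: RegionPartition, n_perm: int = 1000, seed=None
) -> DiffStats:
    """Full differentiation analysis of one marker partition.

    Computes per-locus and pooled Gst/Nst, both permutation tests, and (for
    multilocus data) the delete-one-locus jackknife of the pooled statistics.
    """
    loci = _as_loci(loci)
    per_locus = [gst_nst(ld.haps, ld.delta, part) for ld in loci]
    gst_raw, nst_raw = pooled_gst_nst(loci, part)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    s_region, s_signal = ss.spawn(2)
    p_gst, p_nst = permutation_test_region(loci, part, n_perm=n_perm, seed=s_region)
    p_sig = phylogeo_signal_test(loci, part, n_perm=n_perm, seed=s_signal)
    gst_jack = jackknife_loci(loci, lambda rest: pooled_gst_nst(rest, part)[0])
    nst_jack = jackknife_loci(loci, lambda rest: pooled_gst_nst(rest, part)[1])
    return DiffStats(
        per_locus=per_locus, gst_raw=gst_raw, nst_raw=nst_raw,
        p_gst=p_gst, p_nst=p_nst, p_nst_gt_gst=p_sig,
        gst_jack=gst_jack, nst_jack=nst_jack,
    )
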