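"""Haplotype collapsing and Kimura two-parameter (K2P/K80) distances.

Sequences are collapsed to haplotypes by exact string equality (including
gap/ambiguity characters), and pairwise distances between haplotypes are
computed under the K2P model with pairwise deletion: any site where either
sequence carries a gap, an ambiguity code or N is dropped for that pair
("indels treated as missing data").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import SequenceAlignment
from .errors import InputError, MissingDataError, SaturationError

log = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class HaplotypeAssignment:
    """Distinct sequences of one locus and the individual -> haplotype map."""

    locus_name: str
    haplotype_sequences: list[str]
    assignment: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_sequences)

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def indices(self, ids=None) -> np.ndarray:
        ids = self.ids if ids is None else ids
        return np.array([self.assignment[i] for i in ids], dtype=np.intp)


@dataclass
class AlleleDistanceMatrix:
    """Symmetric matrix of inter-allele distances δij with zero diagonal."""

    delta: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InputError("delta must be square")
        if not np.allclose(np.diagonal(d), 0.0):
            raise InputError("delta must have a zero diagonal")
        finite = np.isfinite(d)  # NaN marks excluded (saturated) pairs
        if not np.array_equal(finite, finite.T) or not np.allclose(
            d[finite], d.T[finite]
        ):
            raise InputError("delta must be symmetric")
        self.delta = d

    @property
    def size(self) -> int:
        return self.delta.shape[0]


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeAssignment:
    """Group identical sequences; haplotypes are ordered by first occurrence."""
    seqs: list[str] = []
    index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for ind, row in zip(aln.ids, aln.rows):
        if row not in index:
            index[row] = len(seqs)
            seqs.append(row)
        assignment[ind] = index[row]
    return HaplotypeAssignment(aln.locus_name, seqs, assignment)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance d = -½·ln(1-2P-Q) - ¼·ln(1-2Q).

    P and Q are the transition and transversion fractions over comparable
    sites (both characters in {A,C,G,T}).  Raises MissingDataError when no
    site is comparable and SaturationError when a log argument is <= 0.
    """
    if len(seq_a) != len(seq_b):
        raise InputError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a in _VALID and b in _VALID:
            n += 1
            if a != b:
                if (a in _PURINES) == (b in _PURINES):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise MissingDataError("no comparable sites")
    p, q = ts / n, tv / n
    if p == 0.0 and q == 0.0:
        return 0.0
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated pair (P={p:.4g}, Q={q:.4g})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def allele_distance_matrix(
    haps: HaplotypeAssignment, on_saturation: str = "raise"
) -> AlleleDistanceMatrix:
    """Pairwise K2P distances between haplotypes.

    on_saturation: "raise" (default) propagates SaturationError naming the
    pair; "na" records NaN for the pair, which downstream distance-weighted
    statistics exclude (with a warning here).
    """
    if haps.n_haplotypes < 1:
        raise InputError("need at least one haplotype")
    if on_saturation not in ("raise", "na"):
        raise InputError("on_saturation must be 'raise' or 'na'")
    h = haps.n_haplotypes
    delta = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            try:
                d = k2p_distance(haps.haplotype_sequences[i], haps.haplotype_sequences[j])
            except (SaturationError, MissingDataError) as err:
                if on_saturation == "raise" or isinstance(err, MissingDataError):
                    raise type(err)(
                        f"locus {haps.locus_name!r}, haplotypes {i} vs {j}: {err}"
                    ) from err
                log.warning(
                    "locus %s: haplotype pair (%d, %d) saturated; excluded from "
                    "distance-weighted statistics", haps.locus_name, i, j,
                )
                d = math.nan
            delta[i, j] = delta[j, i] = d
    return AlleleDistanceMatrix(delta)


def mismatch_matrix(n_haplotypes: int) -> AlleleDistanceMatrix:
    """The unordered-allele distance: δij = 1 for i != j, 0 on the diagonal."""
    return AlleleDistanceMatrix(1.0 - np.eye(n_haplotypes))


def write_distance_tsv(delta: AlleleDistanceMatrix, path, labels=None) -> None:
    labels = labels or [f"h{i}" for i in range(delta.size)]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, delta.delta):
            fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
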