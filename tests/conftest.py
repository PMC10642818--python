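from __future__ import annotations

import warnings

import numpy as np
import pytest

from hapstruct.differentiation import LocusData, RegionPartition
from hapstruct.distances import AlleleDistanceMatrix, HaplotypeAssignment


def make_locus(counts, delta, locus_name="L"):
    """Build a LocusData + RegionPartition from per-region haplotype counts.

    counts: (K, H) integers — individuals of region k carrying haplotype i.
    Dummy distinct sequences stand in for the haplotypes.
    """
    counts = np.asarray(counts, dtype=int)
    K, H = counts.shape
    seqs = ["A" * i + "C" * (H - i) for i in range(H)]
    regions = [f"r{k}" for k in range(K)] if K != 2 else ["north", "south"]
    assignment = {}
    labels = {}
    for k in range(K):
        for h in range(H):
            for c in range(counts[k, h]):
                ind = f"{regions[k]}_{h}_{c}"
                assignment[ind] = h
                labels[ind] = regions[k]
    haps = HaplotypeAssignment(locus_name, seqs, assignment)
    part = RegionPartition(labels)
    return LocusData(haps, AlleleDistanceMatrix(np.asarray(delta, float))), part


@pytest.fixture
def worked_locus():
    """The two-haplotype worked example: A = {h1:2, h2:2}, B = {h1:4}, δ = 0.1."""
    return make_locus([[2, 2], [4, 0]], [[0.0, 0.1], [0.1, 0.0]])


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*monomorphic.*")
        warnings.filterwarnings("ignore", message=".*isolation cap.*")
        yield
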