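"""Gblocks-style removal of ambiguously aligned regions, and cpDNA concatenation.

This is a faithful-parameter re-implementation of the block-selection rules
of Gblocks (v0.91b-era DNA mode), not a bit-exact clone of the original
binary: columns are classified by gap content and residue conservation, long
runs of nonconserved columns are rejected, candidate blocks are trimmed back
to conserved flanks, and short blocks are discarded.

Internally all coordinates are 0-based half-open; log messages print 1-based
inclusive ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

from .core_io import DNA_BASES, SequenceAlignment
from .errors import CleaningError, InputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningParams:
    """Block-selection thresholds.

    min_block_length: shortest block kept after trimming (default 5).
    max_gap_fraction: columns whose gap fraction is >= this are removed
        outright (default 0.5, i.e. keep only columns gapped in <50% of rows).
    max_contiguous_nonconserved: longest tolerated run of nonconserved
        columns (default 8; longer runs are rejected wholesale).
    flank_fraction: residue frequency needed for a block-flank column
        (default 0.85).
    conserved_fraction: residue frequency that must be strictly exceeded for
        a column to count as conserved (default 0.5).
    """

    min_block_length: int = 5
    max_gap_fraction: float = 0.5
    max_contiguous_nonconserved: int = 8
    flank_fraction: float = 0.85
    conserved_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_block_length < 1 or self.max_contiguous_nonconserved < 1:
            raise InputError("count parameters must be >= 1")
        for f in (self.max_gap_fraction, self.flank_fraction, self.conserved_fraction):
            if not (0 < f <= 1):
                raise InputError("fraction parameters must be in (0, 1]")


class PositionStatus(IntEnum):
    GAP_EXCLUDED = 0
    NONCONSERVED = 1
    CONSERVED = 2
    FLANK_CONSERVED = 3  # implies conserved


def classify_positions(
    aln: SequenceAlignment, params: CleaningParams = CleaningParams()
) -> list[PositionStatus]:
    """Classify each column by gap content and conservation.

    A column is gap-excluded when its '-' fraction is >= max_gap_fraction.
    Otherwise let f be the count of the most common unambiguous base (A/C/G/T)
    divided by the total number of rows: the column is conserved when
    f > conserved_fraction and additionally flank-conserved when
    f >= flank_fraction.  Ambiguity codes count toward the row total but are
    never the "most common residue".
    """
    n = aln.n_individuals
    out: list[PositionStatus] = []
    for col in zip(*aln.rows):
        gaps = col.count("-")
        if gaps / n >= params.max_gap_fraction:
            out.append(PositionStatus.GAP_EXCLUDED)
            continue
        best = max((col.count(b) for b in DNA_BASES), default=0)
        f = best / n
        if f >= params.flank_fraction:
            out.append(PositionStatus.FLANK_CONSERVED)
        elif f > params.conserved_fraction:
            out.append(PositionStatus.CONSERVED)
        else:
            out.append(PositionStatus.NONCONSERVED)
    return out


def select_blocks(
    status: Sequence[PositionStatus], params: CleaningParams = CleaningParams()
) -> list[int]:
    """Return the kept 0-based column indices, strictly increasing.

    Steps: (1) drop gap-excluded columns; (2) in the gap-cleaned coordinate
    system, drop runs of more than max_contiguous_nonconserved consecutive
    nonconserved columns; (3) split the survivors into candidate blocks at
    the dropped runs and trim each block's edges back to flank-conserved
    columns; (4) drop blocks shorter than min_block_length.
    """
    kept = [i for i, s in enumerate(status) if s != PositionStatus.GAP_EXCLUDED]

    # (2) runs of nonconserved positions, contiguous after gap cleaning
    drop_run: set[int] = set()
    run: list[int] = []
    for i in kept + [-1]:  # sentinel flushes the last run
        if i >= 0 and status[i] == PositionStatus.NONCONSERVED:
            run.append(i)
        else:
            if len(run) > params.max_contiguous_nonconserved:
                drop_run.update(run)
            run = []

    # (3) candidate blocks are the maximal segments (in gap-cleaned
    # coordinates) not interrupted by a dropped run
    blocks: list[list[int]] = []
    current: list[int] = []
    for i in kept:
        if i in drop_run:
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(i)
    if current:
        blocks.append(current)

    selected: list[int] = []
    for block in blocks:
        lo, hi = 0, len(block) - 1
        while lo <= hi and status[block[lo]] != PositionStatus.FLANK_CONSERVED:
            lo += 1
        while hi >= lo and status[block[hi]] != PositionStatus.FLANK_CONSERVED:
            hi -= 1
        trimmed = block[lo:hi + 1]
        if len(trimmed) >= params.min_block_length:
            selected.extend(trimmed)
    return selected


def clean_alignment(
    aln: SequenceAlignment, params: CleaningParams = CleaningParams()
) -> SequenceAlignment:
    """Restrict the alignment to the selected blocks (ids and row order kept)."""
    status = classify_positions(aln, params)
    kept = select_blocks(status, params)
    if not kept:
        raise CleaningError(
            f"locus {aln.locus_name!r}: no columns survive cleaning "
            f"({aln.n_sites} columns in)"
        )
    ranges = _as_ranges(kept)
    log.info(
        "locus %s: kept %d/%d columns (%s)",
        aln.locus_name, len(kept), aln.n_sites,
        ", ".join(f"{a + 1}-{b + 1}" for a, b in ranges),
    )
    return aln.take_columns(kept)


def _as_ranges(indices: Sequence[int]) -> list[tuple[int, int]]:
    ranges = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i != prev + 1:
            ranges.append((start, prev))
            start = i
        prev = i
    ranges.append((start, prev))
    return ranges


def concatenate_cpdna(alns: Sequence[SequenceAlignment]) -> SequenceAlignment:
    """Concatenate cpDNA loci into the single locus "cpDNA_concat".

    The chloroplast genome is uniparentally inherited and non-recombining, so
    its loci share one genealogy and are analysed as one locus.  Individuals
    absent from a constituent locus receive '-' (missing) for that segment.
    """
    if not alns:
        raise InputError("no cpDNA alignments to concatenate")
    for a in alns:
        if a.genome != "cpDNA":
            raise InputError(f"locus {a.locus_name!r} is not cpDNA")
    if len(alns) == 1:
        a = alns[0]
        return SequenceAlignment("cpDNA_concat", "cpDNA", list(a.ids), list(a.rows))
    ids: list[str] = []
    seen = set()
    for a in alns:
        for i in a.ids:
            if i not in seen:
                seen.add(i)
                ids.append(i)
    segments = []
    for a in alns:
        lookup = dict(zip(a.ids, a.rows))
        blank = "-" * a.n_sites
        segments.append([lookup.get(i, blank) for i in ids])
    rows = ["".join(parts) for parts in zip(*segments)]
    return SequenceAlignment("cpDNA_concat", "cpDNA", ids, rows)
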