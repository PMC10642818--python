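"""Domain types and file I/O.

The pipeline's inputs are per-locus FASTA alignments of haploid sequences
plus two tab-separated tables: sample metadata (one row per individual with
species, group, North/South region, locality and optional coordinates) and a
locus table mapping each locus to its genomic compartment (cpDNA or nDNA).
Outputs are Table-1-style summary tables, one row per species x partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, InputError

GENOMES = ("cpDNA", "nDNA")
GROUPS = ("bryophyte", "spermatophyte")
REGIONS = ("north", "south")

#: Characters treated as unambiguous nucleotides everywhere downstream.
DNA_BASES = frozenset("ACGT")
#: IUPAC one-letter codes accepted in alignments ('-' is the gap/missing state).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class LocusSpec:
    """A locus name together with its genomic compartment."""

    locus_name: str
    genome: str  # "cpDNA" | "nDNA"

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise InputError(f"unknown genome {self.genome!r}; expected one of {GENOMES}")


@dataclass
class SequenceAlignment:
    """A per-locus matrix of aligned haploid sequences.

    Rows are equal-length strings over IUPAC nucleotide codes plus '-'.
    Row order is meaningful only as a stable presentation order; all
    statistics downstream are invariant to it.
    """

    locus_name: str
    genome: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.genome not in GENOMES:
            raise InputError(f"unknown genome {self.genome!r}")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.rows:
            raise InputError(f"empty alignment for locus {self.locus_name!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.locus_name!r}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise InputError(f"locus {self.locus_name!r}: zero-length alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"locus {self.locus_name!r}: duplicate ids {dupes}")
        bad = set("".join(self.rows)) - IUPAC_CODES
        if bad:
            raise InputError(f"locus {self.locus_name!r}: non-IUPAC characters {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def take_columns(self, indices: Sequence[int]) -> "SequenceAlignment":
        """New alignment restricted to the given 0-based columns (order kept)."""
        rows = ["".join(r[i] for i in indices) for r in self.rows]
        return SequenceAlignment(self.locus_name, self.genome, list(self.ids), rows)

    def subset(self, keep_ids: Iterable[str]) -> "SequenceAlignment":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        if not pairs:
            raise InputError(f"locus {self.locus_name!r}: subset removed every individual")
        ids, rows = map(list, zip(*pairs))
        return SequenceAlignment(self.locus_name, self.genome, ids, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


def read_alignment(path, locus: LocusSpec) -> SequenceAlignment:
    """Read one FASTA alignment; ids are headers up to the first whitespace.

    Rows are upper-cased and record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return SequenceAlignment(locus.locus_name, locus.genome, ids, rows)


METADATA_COLUMNS = ("id", "species", "group", "region", "locality", "lat", "lon")


@dataclass
class SampleMetadata:
    """Per-individual metadata backed by a pandas DataFrame.

    Columns: id, species, group (bryophyte|spermatophyte), region
    (north|south), locality, lat, lon.  Coordinates are optional but must be
    both present or both absent per individual.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"metadata missing required columns {missing}")
        t = self.table
        if t["id"].duplicated().any():
            raise InputError(f"duplicate metadata ids: {sorted(t['id'][t['id'].duplicated()])}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise InputError(f"unknown group values {sorted(bad_group)}")
        bad_region = set(t["region"].dropna()) - set(REGIONS)
        if bad_region:
            raise InputError(f"unknown region values {sorted(bad_region)}")
        lat, lon = t["lat"], t["lon"]
        if (lat.notna() != lon.notna()).any():
            raise InputError("latitude/longitude must be both present or both absent")
        if ((lat.dropna().abs() > 90).any()) or ((lon.dropna().abs() > 180).any()):
            raise InputError("coordinates out of range")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def region_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["region"]))

    def coords_of(self) -> dict[str, tuple[float, float]]:
        out = {}
        for _, row in self.table.iterrows():
            if pd.notna(row["lat"]):
                out[row["id"]] = (float(row["lat"]), float(row["lon"]))
        return out

    def has_coordinates(self) -> bool:
        return bool(self.table["lat"].notna().any())


def read_metadata(path) -> SampleMetadata:
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "locality": str})
    return SampleMetadata(t)


def read_locus_table(path) -> list[LocusSpec]:
    t = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("locus_name", "genome"):
        if col not in t.columns:
            raise InputError(f"locus table missing column {col!r}")
    names = list(t["locus_name"])
    if len(set(names)) != len(names):
        raise InputError("duplicate locus names in locus table")
    return [LocusSpec(n, g) for n, g in zip(t["locus_name"], t["genome"])]


@dataclass
class ValidationReport:
    """Advisory dataset-selection report (minimum-sample rule)."""

    low_sample_loci: dict[str, int] = field(default_factory=dict)
    ids_without_region: list[str] = field(default_factory=list)
    excluded: bool = False
    min_n: int = 15

    def __str__(self) -> str:
        parts = [f"min_n={self.min_n}", f"excluded={self.excluded}"]
        if self.low_sample_loci:
            parts.append("low-sample loci: " + ", ".join(
                f"{k} (n={v})" for k, v in self.low_sample_loci.items()))
        if self.ids_without_region:
            parts.append(f"{len(self.ids_without_region)} ids lack region labels")
        return "; ".join(parts)


def validate_dataset(
    aln_set: Sequence[SequenceAlignment], meta: SampleMetadata, min_n: int = 15
) -> ValidationReport:
    """Apply the study-selection rule: every locus needs >= min_n individuals.

    Exclusion is advisory; the pipeline can override it.  An individual that
    appears in an alignment but not in the metadata is a hard error.
    """
    if min_n < 1:
        raise InputError("min_n must be >= 1")
    known = set(meta.ids)
    region = meta.region_of()
    report = ValidationReport(min_n=min_n)
    no_region: set[str] = set()
    for aln in aln_set:
        unknown = [i for i in aln.ids if i not in known]
        if unknown:
            raise InputError(
                f"locus {aln.locus_name!r}: ids absent from metadata: {sorted(unknown)[:5]}"
            )
        if aln.n_individuals < min_n:
            report.low_sample_loci[aln.locus_name] = aln.n_individuals
        no_region.update(i for i in aln.ids if pd.isna(region.get(i)))
    report.ids_without_region = sorted(no_region)
    report.excluded = bool(report.low_sample_loci)
    return report


@dataclass
class SpeciesSummary:
    """One Table-1-style row: a species x marker-partition summary."""

    species: str
    group: str
    partition: str  # "cpDNA" | "nDNA" | "both"
    n_individuals: int
    n_loci: int
    gst: Optional[float] = None
    p_gst: Optional[float] = None
    gst_jack_mean: Optional[float] = None
    gst_jack_halfwidth: Optional[float] = None
    nst: Optional[float] = None
    p_nst: Optional[float] = None
    nst_jack_mean: Optional[float] = None
    nst_jack_halfwidth: Optional[float] = None
    p_nst_gt_gst: Optional[float] = None


_SUMMARY_STATS = (
    "gst", "p_gst", "gst_jack_mean", "gst_jack_halfwidth",
    "nst", "p_nst", "nst_jack_mean", "nst_jack_halfwidth", "p_nst_gt_gst",
)


def _fmt2(x: Optional[float]) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.2f}"


def _fmt_full(x: Optional[float]) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else repr(float(x))


def write_summary_table(rows: Sequence[SpeciesSummary], path) -> None:
    """Write summary rows as TSV.

    Display columns are rounded to 2 decimals with jackknife shown as
    "mean ± halfwidth"; a parallel ``*_exact`` column set keeps full
    precision.  NA is rendered literally.
    """
    if not rows:
        raise InputError("no summary rows to write")
    header = [
        "species", "group", "partition", "n_individuals", "n_loci",
        "Gst", "P-Gst", "Gst-Jack", "Nst", "P-Nst", "Nst-Jack", "P(Nst>Gst)",
    ] + [f"{s}_exact" for s in _SUMMARY_STATS]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            jack_g = ("NA" if r.gst_jack_mean is None
                      else f"{_fmt2(r.gst_jack_mean)} ± {_fmt2(r.gst_jack_halfwidth)}")
            jack_n = ("NA" if r.nst_jack_mean is None
                      else f"{_fmt2(r.nst_jack_mean)} ± {_fmt2(r.nst_jack_halfwidth)}")
            cells = [
                r.species, r.group, r.partition, str(r.n_individuals), str(r.n_loci),
                _fmt2(r.gst), _fmt2(r.p_gst), jack_g,
                _fmt2(r.nst), _fmt2(r.p_nst), jack_n, _fmt2(r.p_nst_gt_gst),
            ] + [_fmt_full(getattr(r, s)) for s in _SUMMARY_STATS]
            fh.write("\t".join(cells) + "\n")
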