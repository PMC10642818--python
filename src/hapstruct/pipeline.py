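"""Orchestration: per-species analysis, comparative synthesis, sim studies.

A species dataset is a set of per-locus alignments plus sample metadata.
`run_species` executes the full chain — validation, Gblocks-style cleaning,
cpDNA concatenation, haplotype collapsing, K2P distances, Gst/Nst with
permutation and phylogeographic-signal tests and the locus jackknife for
the cpDNA / nDNA / combined partitions, then kinship and isolation-by-
distance regressions per region.  `run_comparative` synthesizes many
species into group comparisons, and `full_sim_study` re-enacts the whole
design on simulated bryophyte-like vs spermatophyte-like species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import comparative
from .cleaning import CleaningParams, clean_alignment, concatenate_cpdna
from .core_io import (
    SampleMetadata, SequenceAlignment, SpeciesSummary, ValidationReport,
    read_alignment, read_metadata, validate_dataset, LocusSpec,
)
from .differentiation import LocusData, RegionPartition, analyze_partition
from .distances import allele_distance_matrix, collapse_haplotypes
from .errors import HapstructError, InputError
from .kinship import (
    distance_matrix_km, ibd_regression, ibd_slope_jackknife, loiselle_kinship,
)

log = logging.getLogger(__name__)

PARTITIONS = ("cpDNA", "nDNA", "both")


@dataclass
class RunConfig:
    """Pipeline-wide knobs; defaults mirror the study conditions."""

    cleaning: Optional[CleaningParams] = field(default_factory=CleaningParams)
    n_perm: int = 1000
    alpha: float = 0.05
    min_n: int = 15
    override_min_n: bool = False
    exclusions: Sequence[tuple[str, str]] = comparative.DEFAULT_EXCLUSIONS
    saturation: str = "raise"  # "raise" | "na"
    mantel_alternative: str = "less"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise InputError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise InputError("alpha must be in (0, 1)")


@dataclass
class SpeciesDataset:
    name: str
    group: str
    alignments: list[SequenceAlignment]
    metadata: SampleMetadata


def load_species_dataset(directory, name: str = None, group: str = None) -> SpeciesDataset:
    """Load the on-disk dataset convention: loci.tsv + metadata.tsv + FASTAs."""
    d = Path(directory)
    loci = pd.read_csv(d / "loci.tsv", sep="\t")
    meta = read_metadata(d / "metadata.tsv")
    alns = [
        read_alignment(d / row["path"], LocusSpec(row["locus_name"], row["genome"]))
        for _, row in loci.iterrows()
    ]
    name = name or str(meta.table["species"].iloc[0])
    group = group or str(meta.table["group"].iloc[0])
    return SpeciesDataset(name=name, group=group, alignments=alns, metadata=meta)


@dataclass
class SpeciesResult:
    name: str
    group: str
    validation: ValidationReport
    summaries: list[SpeciesSummary]
    ibd: pd.DataFrame  # long format: partition, region, scale, slope, r2, ...


def _partition_loci(
    cp: Optional[SequenceAlignment], nuclear: list[SequenceAlignment], partition: str
) -> list[SequenceAlignment]:
    if partition == "cpDNA":
        return [cp] if cp is not None else []
    if partition == "nDNA":
        return list(nuclear)
    return ([cp] if cp is not None else []) + list(nuclear)


def run_species(
    cfg: RunConfig, dataset: SpeciesDataset
) -> Optional[SpeciesResult]:
    """Analyse one species; returns None (with a logged reason) on failure."""
    try:
        return _run_species(cfg, dataset)
    except HapstructError as err:
        log.error("species %s aborted: %s", dataset.name, err)
        return None


def _run_species(cfg: RunConfig, dataset: SpeciesDataset) -> Optional[SpeciesResult]:
    meta = dataset.metadata
    report = validate_dataset(dataset.alignments, meta, min_n=cfg.min_n)
    if report.excluded and not cfg.override_min_n:
        log.warning("species %s excluded by the minimum-sample rule: %s",
                    dataset.name, report)
        return SpeciesResult(dataset.name, dataset.group, report, [], pd.DataFrame())

    alns = dataset.alignments
    if cfg.cleaning is not None:
        alns = [clean_alignment(a, cfg.cleaning) for a in alns]
    cp_parts = [a for a in alns if a.genome == "cpDNA"]
    nuclear = [a for a in alns if a.genome == "nDNA"]
    cp = concatenate_cpdna(cp_parts) if cp_parts else None

    ss = np.random.SeedSequence(cfg.seed)
    seeds = iter(ss.generate_state(64))

    summaries: list[SpeciesSummary] = []
    locus_cache: dict[str, LocusData] = {}

    def as_locus_data(aln: SequenceAlignment) -> LocusData:
        if aln.locus_name not in locus_cache:
            haps = collapse_haplotypes(aln)
            delta = allele_distance_matrix(haps, on_saturation=cfg.saturation)
            locus_cache[aln.locus_name] = LocusData(haps, delta)
        return locus_cache[aln.locus_name]

    for partition in PARTITIONS:
        part_alns = _partition_loci(cp, nuclear, partition)
        if not part_alns or (partition == "both" and (cp is None or not nuclear)):
            continue
        loci = [as_locus_data(a) for a in part_alns]
        ids = sorted({i for a in part_alns for i in a.ids})
        part = RegionPartition.from_metadata(meta, ids=ids)
        stats = analyze_partition(loci, part, n_perm=cfg.n_perm, seed=int(next(seeds)))
        summaries.append(SpeciesSummary(
            species=dataset.name, group=dataset.group, partition=partition,
            n_individuals=len(ids), n_loci=len(loci),
            gst=stats.gst, p_gst=stats.p_gst,
            gst_jack_mean=None if stats.gst_jack is None else stats.gst_jack.mean,
            gst_jack_halfwidth=None if stats.gst_jack is None else stats.gst_jack.halfwidth,
            nst=stats.nst, p_nst=stats.p_nst,
            nst_jack_mean=None if stats.nst_jack is None else stats.nst_jack.mean,
            nst_jack_halfwidth=None if stats.nst_jack is None else stats.nst_jack.halfwidth,
            p_nst_gt_gst=stats.p_nst_gt_gst,
        ))
        log.info("species %s %s: %d loci, %d individuals",
                 dataset.name, partition, len(loci), len(ids))

    ibd_rows = []
    coords = meta.coords_of()
    if coords:
        region_of = meta.region_of()
        for partition in ("cpDNA", "nDNA"):
            part_alns = _partition_loci(cp, nuclear, partition)
            if not part_alns:
                continue
            haps_list = [locus_cache[a.locus_name].haps
                         if a.locus_name in locus_cache else collapse_haplotypes(a)
                         for a in part_alns]
            for region in ("south", "north"):
                ids = sorted({
                    i for a in part_alns for i in a.ids
                    if region_of.get(i) == region and i in coords
                })
                if len(ids) < 3:
                    log.info("species %s %s/%s: <3 placed individuals, IBD skipped "
                             "(missing geographic coordinates)",
                             dataset.name, partition, region)
                    continue
                kin = loiselle_kinship(haps_list, ids)
                dists = distance_matrix_km(ids, coords)
                for scale in ("linear", "log"):
                    res = ibd_regression(
                        kin, dists, scale=scale, n_perm=cfg.n_perm,
                        seed=int(next(seeds)), alternative=cfg.mantel_alternative,
                    )
                    jack = (ibd_slope_jackknife(haps_list, ids, dists, scale)
                            if len(haps_list) >= 2 else None)
                    ibd_rows.append({
                        "species": dataset.name, "group": dataset.group,
                        "partition": partition, "region": region, "scale": scale,
                        "slope": res.slope, "intercept": res.intercept,
                        "r2": res.r2, "mantel_p": res.mantel_p,
                        "n_pairs": res.n_pairs,
                        "slope_jack_mean": None if jack is None else jack.mean,
                        "slope_jack_halfwidth": None if jack is None else jack.halfwidth,
                    })
    return SpeciesResult(dataset.name, dataset.group, report, summaries,
                         pd.DataFrame(ibd_rows))


@dataclass
class ComparativeReport:
    comparisons: list
    counts: pd.DataFrame
    scale_tests: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def run_comparative(
    summary_rows: pd.DataFrame,
    ibd_rows: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    exclusions: Sequence[tuple[str, str]] = comparative.DEFAULT_EXCLUSIONS,
) -> ComparativeReport:
    """Group synthesis: Welch tests, significant-test counts, r² scale test."""
    comparisons = []
    skipped = []
    for stat in ("gst", "nst"):
        for partition in PARTITIONS:
            try:
                comparisons.append(comparative.compare_groups(
                    summary_rows, stat, partition, exclusions=exclusions))
            except InputError as err:
                skipped.append(f"{stat}/{partition}: {err}")
    count_rows = []
    for group in ("bryophyte", "spermatophyte"):
        for partition in PARTITIONS:
            for column in ("p_gst", "p_nst", "p_nst_gt_gst"):
                count_rows.append({
                    "group": group, "partition": partition, "column": column,
                    "n_significant": comparative.count_significant(
                        summary_rows, partition, group, column, alpha=alpha),
                })
    scale_rows = []
    if ibd_rows is not None and len(ibd_rows):
        from .kinship import compare_scales

        for group in sorted(ibd_rows["group"].unique()):
            for region in sorted(ibd_rows["region"].unique()):
                sel = ibd_rows[(ibd_rows["group"] == group)
                               & (ibd_rows["region"] == region)
                               & (ibd_rows["partition"] == "cpDNA")]
                lin = sel[sel["scale"] == "linear"].set_index("species")["r2"]
                lg = sel[sel["scale"] == "log"].set_index("species")["r2"]
                common = lin.index.intersection(lg.index)
                if len(common) < 2:
                    skipped.append(f"scale test {group}/{region}: <2 species")
                    continue
                res = compare_scales(lin[common], lg[common])
                scale_rows.append({
                    "group": group, "region": region, "n_species": res.n,
                    "r2_linear_mean": res.mean_linear, "r2_linear_sd": res.sd_linear,
                    "r2_log_mean": res.mean_log, "r2_log_sd": res.sd_log,
                    "t": res.t, "df": res.df, "p": res.p_two_sided,
                })
    return ComparativeReport(
        comparisons=comparisons, counts=pd.DataFrame(count_rows),
        scale_tests=pd.DataFrame(scale_rows), skipped=skipped,
    )


def full_sim_study(
    n_per_group: int = 5,
    n_perm: int = 200,
    seed: Optional[int] = None,
    samples_per_deme: int = 15,
) -> tuple[pd.DataFrame, ComparativeReport]:
    """Desk-scale re-enactment of the comparative design on simulated species.

    Bryophyte-like species: spores carry both genomes and disperse well, so
    cpDNA and nDNA see the same high migration (2Nm = 8).  Spermatophyte-like
    species: pollen keeps nuclear gene flow high (2Nm = 8) but seeds move
    cpDNA poorly, modelled by an eightfold smaller chloroplast Ne·m
    (cp_to_nuclear_ne_ratio = 0.125, i.e. cp 2Nm = 1).
    """
    from .simulate import simulate_dataset

    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(4 * n_per_group + 1))
    cfg = RunConfig(cleaning=None, n_perm=n_perm, min_n=1)
    all_summaries: list[SpeciesSummary] = []
    for group, ne_ratio in (("bryophyte", 1.0), ("spermatophyte", 0.125)):
        for k in range(n_per_group):
            name = f"sim_{group}_{k}"
            ds = simulate_dataset(
                scenario="island_migration", seed=int(next(seeds)) % 2**31,
                species=name, group=group,
                migration=8.0 / (2.0 * 1000.0),
                cp_to_nuclear_ne_ratio=ne_ratio,
                # mu chosen so even the reduced-Ne chloroplast stays
                # polymorphic (theta_cp = 0.5 in the spermatophyte-like group)
                mu=4e-6,
                n_nuclear_loci=2, samples_per_deme=samples_per_deme,
            )
            run_cfg = RunConfig(cleaning=None, n_perm=n_perm, min_n=cfg.min_n,
                                seed=int(next(seeds)) % 2**31)
            res = run_species(run_cfg, SpeciesDataset(
                name=name, group=group, alignments=ds.alignments,
                metadata=ds.metadata))
            if res is not None:
                all_summaries.extend(res.summaries)
    frame = comparative.summaries_to_frame(all_summaries)
    report = run_comparative(frame, exclusions=())
    return frame, report
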