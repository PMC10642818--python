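"""Structured-coalescent simulator for two-region haploid sequence datasets.

The generator emulates the statistical structure the analysis assumes: demes
of haploid individuals partitioned into a northern and a southern region,
one non-recombining "cpDNA" locus (all concatenated chloroplast sites share
a single genealogy) plus independent nuclear loci, two-parameter (K2P-type)
substitutions with a transition/transversion rate ratio kappa, migration
tunable from panmixia to complete isolation, and deme coordinates on a
~1500 km lat/lon layout so isolation-by-distance slopes are on a realistic
per-km scale.

Genealogies are drawn backward in time with exact exponential event times:
within a deme holding k lineages, coalescence occurs at rate k(k-1)/2 / Ne
per generation; each lineage migrates at rate m, to any other deme (island
topology) or to an adjacent deme (1-D stepping stone).  Mutations are laid
down as a Poisson process along branches; each substitution is a transition
with probability kappa/(kappa+2), otherwise one of the two transversions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import SampleMetadata, SequenceAlignment
from .errors import InputError

SCENARIOS = ("panmixia", "island_migration", "two_region_isolation", "stepping_stone_ibd")


@dataclass
class SimConfig:
    """Parameters of one simulated species-like dataset.

    deme_size is the haploid effective size N per deme; migration is the
    per-generation per-lineage migration probability m; mu the per-site
    per-generation substitution rate; kappa the transition/transversion rate
    ratio.  cp_to_nuclear_ne_ratio scales Ne for the cpDNA locus (default 1).
    region_split maps deme index -> "north"/"south"; coordinates gives one
    (lat, lon) per deme, jittered per individual on output.
    """

    n_demes: int = 1
    deme_size: float = 1000.0
    migration: float = 0.0
    topology: str = "island"  # "island" | "stepping_stone_1d"
    samples_per_deme: int = 30
    seq_length: int = 500
    mu: float = 5e-6
    kappa: float = 2.0
    n_nuclear_loci: int = 1
    cp_to_nuclear_ne_ratio: float = 1.0
    region_split: Optional[dict[int, str]] = None
    coordinates: Optional[list[tuple[float, float]]] = None
    coordinate_jitter_deg: float = 0.05
    allow_incomplete_coalescence: bool = False
    isolation_cap_generations: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n_demes, self.samples_per_deme, self.seq_length,
               self.n_nuclear_loci + 1) < 1:
            raise InputError("counts must be >= 1")
        if not (0.0 <= self.migration <= 1.0):
            raise InputError("migration must be in [0, 1]")
        if self.mu < 0 or self.kappa <= 0 or self.cp_to_nuclear_ne_ratio <= 0:
            raise InputError("mu >= 0, kappa > 0, Ne ratio > 0 required")
        if self.topology not in ("island", "stepping_stone_1d"):
            raise InputError(f"unknown topology {self.topology!r}")


@dataclass
class Genealogy:
    """A binary coalescent tree over n sampled lineages.

    Nodes 0..n-1 are samples (time 0); internal nodes follow in coalescence
    order; node 2n-2 is the root.  parent[root] = -1.
    """

    n_samples: int
    parent: np.ndarray
    time: np.ndarray
    children: list[tuple[int, int]] = field(repr=False)  # per internal node

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])


def _neighbors(deme: int, n_demes: int, topology: str) -> list[int]:
    if topology == "island":
        return [d for d in range(n_demes) if d != deme]
    out = []
    if deme > 0:
        out.append(deme - 1)
    if deme < n_demes - 1:
        out.append(deme + 1)
    return out


def simulate_genealogy(
    cfg: SimConfig, locus_kind: str = "nDNA", rng: Optional[np.random.Generator] = None
) -> Genealogy:
    """Draw one genealogy under the structured coalescent.

    With migration = 0 and samples spread over several demes, lineages can
    never meet; this is refused unless allow_incomplete_coalescence is set,
    in which case all surviving lineages are pooled into one ancestral deme
    at isolation_cap_generations and the coalescent continues there (deep
    isolation with a panmictic ancestor).
    """
    if locus_kind not in ("cpDNA", "nDNA"):
        raise InputError(f"unknown locus kind {locus_kind!r}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_demes * cfg.samples_per_deme
    ne = cfg.deme_size * (cfg.cp_to_nuclear_ne_ratio if locus_kind == "cpDNA" else 1.0)
    deme_of = {node: d for d in range(cfg.n_demes)
               for node in range(d * cfg.samples_per_deme, (d + 1) * cfg.samples_per_deme)}
    if cfg.migration == 0.0 and cfg.n_demes > 1:
        if not cfg.allow_incomplete_coalescence:
            raise InputError(
                "migration = 0 with samples in several demes: lineages cannot "
                "coalesce; set allow_incomplete_coalescence and an isolation cap"
            )
        if cfg.isolation_cap_generations is None:
            raise InputError("allow_incomplete_coalescence requires an isolation cap")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    children: list[tuple[int, int]] = []
    active = list(range(n))
    t = 0.0
    next_node = n
    cap = cfg.isolation_cap_generations
    capped = False

    while len(active) > 1:
        by_deme: dict[int, list[int]] = {}
        for node in active:
            by_deme.setdefault(deme_of[node], []).append(node)
        coal_rates = {d: len(v) * (len(v) - 1) / 2.0 / ne for d, v in by_deme.items()}
        coal_total = sum(coal_rates.values())
        mig_total = cfg.migration * len(active) if cfg.n_demes > 1 and not capped else 0.0
        total = coal_total + mig_total
        if total == 0.0:
            # isolated singletons; jump to the cap and pool
            if cap is None:
                raise InputError("stuck genealogy without an isolation cap")
            t = max(t, cap)
            for node in active:
                deme_of[node] = 0
            capped = True
            warnings.warn("isolation cap reached; remaining lineages pooled")
            continue
        dt = rng.exponential(1.0 / total)
        if cap is not None and not capped and t + dt >= cap:
            t = cap
            for node in active:
                deme_of[node] = 0
            capped = True
            continue
        t += dt
        if rng.random() < coal_total / total:
            demes, weights = zip(*coal_rates.items())
            d = demes[rng.choice(len(demes), p=np.asarray(weights) / coal_total)]
            pair = rng.choice(len(by_deme[d]), size=2, replace=False)
            a, b = by_deme[d][pair[0]], by_deme[d][pair[1]]
            parent[a] = parent[b] = next_node
            time[next_node] = t
            children.append((a, b))
            deme_of[next_node] = d
            active = [x for x in active if x not in (a, b)] + [next_node]
            next_node += 1
        else:
            node = active[rng.integers(len(active))]
            nb = _neighbors(deme_of[node], cfg.n_demes, cfg.topology)
            deme_of[node] = nb[rng.integers(len(nb))]
    return Genealogy(n_samples=n, parent=parent, time=time, children=children)


_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T with A,C,G,T = 0..3
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_BASES = np.array(list("ACGT"))


def mutate_sequences(
    gen: Genealogy,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ids: Optional[Sequence[str]] = None,
    locus_name: str = "locus",
    genome: str = "nDNA",
) -> SequenceAlignment:
    """Drop K2P-type mutations on a genealogy and emit the leaf alignment.

    The root sequence is uniform over {A,C,G,T}; each branch receives
    Poisson(mu · L · branch length) substitutions at uniformly chosen sites
    (multiple hits allowed); a substitution is a transition with probability
    kappa/(kappa+2), else one of the two transversions equiprobably.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    L = cfg.seq_length
    n = gen.n_samples
    p_ts = cfg.kappa / (cfg.kappa + 2.0)
    seqs: dict[int, np.ndarray] = {2 * n - 2: rng.integers(0, 4, size=L)}
    # walk internal nodes root-ward -> tip-ward (children list is in
    # coalescence order, so reversed order visits parents first)
    for node in range(2 * n - 2, n - 1, -1):
        a, b = gen.children[node - n]
        for child in (a, b):
            seq = seqs[node].copy()
            brlen = gen.time[node] - gen.time[child]
            n_mut = rng.poisson(cfg.mu * L * brlen)
            for site in rng.integers(0, L, size=n_mut):
                cur = seq[site]
                if rng.random() < p_ts:
                    seq[site] = _TRANSITION[cur]
                else:
                    seq[site] = _TRANSVERSIONS[cur][rng.integers(2)]
            seqs[child] = seq
        del seqs[node]
    ids = list(ids) if ids is not None else [f"s{i:04d}" for i in range(n)]
    rows = ["".join(_BASES[seqs[i]]) for i in range(n)]
    return SequenceAlignment(locus_name, genome, ids, rows)


def scenario_config(scenario: str, seed: Optional[int] = None, **overrides) -> SimConfig:
    """Preset configurations for the four study conditions.

    panmixia: one deme, no structure; individuals get arbitrary alternating
        North/South labels and scattered coordinates (null for both the
        region permutation test and the Mantel test).
    island_migration: two demes (North/South) exchanging migrants; override
        `migration` (default m = 1/(2N), i.e. M = 2Nm = 1).
    two_region_isolation: two demes, m = 0, deep isolation capped at 20N
        generations with a low mutation rate, so regions carry private,
        region-clustered alleles (strong differentiation and signal).
    stepping_stone_ibd: ten demes on a ~1500 km line with nearest-neighbour
        migration, producing isolation by distance.
    """
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    base: dict = dict(seed=seed)
    if scenario == "panmixia":
        base.update(
            n_demes=1, samples_per_deme=30, deme_size=1000.0, migration=0.0,
            mu=5e-6, seq_length=500, coordinates=[(45.0, 5.0)],
            coordinate_jitter_deg=1.5, region_split={0: "south"},
        )
    elif scenario == "island_migration":
        base.update(
            n_demes=2, samples_per_deme=15, deme_size=1000.0,
            migration=1.0 / (2.0 * 1000.0), topology="island",
            mu=5e-7, seq_length=500,
            region_split={0: "south", 1: "north"},
            coordinates=[(41.0, 3.0), (48.0, 5.0)],
        )
    elif scenario == "two_region_isolation":
        base.update(
            n_demes=2, samples_per_deme=15, deme_size=1000.0, migration=0.0,
            mu=2.5e-7, seq_length=500, n_nuclear_loci=2,
            allow_incomplete_coalescence=True,
            isolation_cap_generations=20.0 * 1000.0,
            region_split={0: "south", 1: "north"},
            coordinates=[(41.0, 3.0), (48.0, 5.0)],
        )
    else:  # stepping_stone_ibd
        base.update(
            n_demes=10, samples_per_deme=3, deme_size=1000.0, migration=5e-4,
            topology="stepping_stone_1d", mu=5e-6, seq_length=500,
            region_split={d: ("south" if d < 5 else "north") for d in range(10)},
            coordinates=[(45.0, 2.0 * d) for d in range(10)],
        )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimulatedDataset:
    alignments: list[SequenceAlignment]  # cpDNA locus first, then nuclear loci
    metadata: SampleMetadata
    config: SimConfig

    @property
    def cpdna(self) -> SequenceAlignment:
        return self.alignments[0]

    @property
    def nuclear(self) -> list[SequenceAlignment]:
        return self.alignments[1:]


def simulate_dataset(
    cfg: Optional[SimConfig] = None,
    scenario: Optional[str] = None,
    seed: Optional[int] = None,
    species: str = "sim_species",
    group: str = "bryophyte",
    **overrides,
) -> SimulatedDataset:
    """Simulate a full species-like dataset: cpDNA + nuclear loci + metadata.

    Either pass a SimConfig or a scenario name (with optional overrides).
    The cpDNA genealogy is drawn once (non-recombining, all sites share it);
    each nuclear locus gets an independent genealogy.  Fully reproducible
    from the seed.
    """
    if cfg is None:
        if scenario is None:
            raise InputError("need a SimConfig or a scenario name")
        cfg = scenario_config(scenario, seed=seed, **overrides)
    elif seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_demes * cfg.samples_per_deme
    ids = [f"{species}_{i:04d}" for i in range(n)]

    gen_cp = simulate_genealogy(cfg, "cpDNA", rng)
    alns = [mutate_sequences(gen_cp, cfg, rng, ids=ids, locus_name="cp1", genome="cpDNA")]
    for l in range(cfg.n_nuclear_loci):
        gen = simulate_genealogy(cfg, "nDNA", rng)
        alns.append(mutate_sequences(gen, cfg, rng, ids=ids,
                                     locus_name=f"nuc{l + 1}", genome="nDNA"))

    deme_idx = np.repeat(np.arange(cfg.n_demes), cfg.samples_per_deme)
    split = cfg.region_split or {d: "south" for d in range(cfg.n_demes)}
    if cfg.n_demes == 1 and len(set(split.values())) == 1:
        # single-deme null: arbitrary alternating labels, 50/50
        regions = ["south" if i % 2 == 0 else "north" for i in range(n)]
    else:
        regions = [split[int(d)] for d in deme_idx]
    if cfg.coordinates is not None:
        lat0 = np.array([cfg.coordinates[d][0] for d in deme_idx])
        lon0 = np.array([cfg.coordinates[d][1] for d in deme_idx])
        j = cfg.coordinate_jitter_deg
        lats = lat0 + rng.uniform(-j, j, size=n)
        lons = lon0 + rng.uniform(-j, j, size=n)
    else:
        lats = lons = np.full(n, np.nan)
    meta = SampleMetadata(pd.DataFrame({
        "id": ids, "species": species, "group": group, "region": regions,
        "locality": [f"deme{d}" for d in deme_idx], "lat": lats, "lon": lons,
    }))
    return SimulatedDataset(alignments=alns, metadata=meta, config=cfg)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write FASTA per locus, metadata.tsv, loci.tsv and sim-config.json."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    locus_rows = []
    for aln in ds.alignments:
        aln.to_fasta(out / f"{aln.locus_name}.fasta")
        locus_rows.append({"locus_name": aln.locus_name, "genome": aln.genome,
                           "path": f"{aln.locus_name}.fasta"})
    pd.DataFrame(locus_rows).to_csv(out / "loci.tsv", sep="\t", index=False)
    ds.metadata.table.to_csv(out / "metadata.tsv", sep="\t", index=False)
    cfg = asdict(ds.config)
    if cfg["region_split"] is not None:
        cfg["region_split"] = {str(k): v for k, v in cfg["region_split"].items()}
    (out / "sim-config.json").write_text(json.dumps(cfg, indent=2, default=float))
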