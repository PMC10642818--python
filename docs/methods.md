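# Methods

## Scope and data model

`hapstruct` analyses haploid sequence datasets: per-locus FASTA alignments
of individuals annotated with species, taxonomic group (bryophyte /
spermatophyte), a two-level region label (north/south of a dispersal
barrier) and optional coordinates. All statistics operate on haplotypes —
distinct sequences under exact string equality, including gap and
ambiguity characters. Exact matching is deterministic and
order-independent; it deliberately avoids ambiguous-merge heuristics, at
the cost of splitting haplotypes that differ only in missing data.
Region assignment is metadata input and is never inferred from
coordinates: which side of a barrier a locality belongs to is a study
design choice, not a computation.

## Alignment cleaning

Ambiguously aligned regions are removed with a faithful-parameter
re-implementation of the Gblocks (v0.91b-era, DNA mode) block filter, not
a bit-exact clone of the binary. Defaults: positions gapped in ≥ 50 % of
sequences are removed; a position is *conserved* when its most frequent
unambiguous base occurs in strictly more than 50 % of all rows and a
*flank* position at ≥ 85 %; runs of more than 8 contiguous nonconserved
positions are rejected; blocks are trimmed to flank-conserved ends and
kept only at length ≥ 5. The conserved threshold is the tool's default
rule; the other four numbers are the published parameterization this
pipeline mirrors. Ambiguity codes count toward the row total but can never
be the majority residue (conservative). Coordinates are 0-based half-open
internally; logs print 1-based inclusive ranges. The filter is idempotent
and its kept set is invariant to row order; relaxing the run-length or
block-length thresholds can only grow the kept set (all three are
property-tested).

Chloroplast loci are concatenated after cleaning and analysed as a single
locus — the organellar genome is uniparentally inherited and effectively
non-recombining, so its loci share one genealogy. Whether cleaning should
precede or follow concatenation is not determined by the concatenation
model; cleaning per locus first keeps per-locus gap structure local and is
the default. Individuals missing a constituent locus are padded with
missing characters.

## Distances

Inter-haplotype distances use the Kimura two-parameter model,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with pairwise deletion: a site
contributes only when both sequences carry an unambiguous base, so indels
and ambiguity codes act as missing data. Saturation (a non-positive log
argument) raises by default; an opt-in policy records the pair as NA, and
distance-weighted statistics then exclude those terms with a warning.
The implementation is cross-checked in the test suite against an
independent oracle (R `ape::dist.dna(model = "K80",
pairwise.deletion = TRUE)`) on a random gapped alignment.

## Differentiation (Gst, Nst) and inference

Diversity components follow the Pons & Petit ordered/unordered-allele
estimators, written for K ≥ 2 regions (the pipeline uses K = 2):
v̂_k = n_k/(n_k−1) Σᵢⱼ x_ik x_jk δᵢⱼ over ordered haplotype pairs,
v̂S the unweighted mean over regions, and
v̂T = Σᵢⱼ x̄ᵢ x̄ⱼ δᵢⱼ + v̂S/(K·ñ) with ñ the harmonic mean sample size.
Nst = (v̂T − v̂S)/v̂T with the K2P δ; Gst uses the mismatch indicator, so
its components are the classical hS/hT. When every off-diagonal δ is
equal the two statistics coincide exactly — an algebraic identity used as
a test invariant. Raw (possibly negative) estimates are retained
internally; display values clamp at zero, which is also how published
tables render them. Monomorphic partitions (v̂T = 0) report NA.

Multilocus statistics pool loci by ratio of sums,
Σ_l (v̂T − v̂S) / Σ_l v̂T; individuals unscored at a locus are dropped
from that locus only. Per-locus statistics are reported alongside. The
delete-one-locus jackknife gives SE = √(((L−1)/L) Σ_l (θ₍₋l₎ − θ̄)²),
reported as mean ± 1.96 SE, and is NA for single-locus data.

Two permutation tests, 1000 replicates by default, both with the add-one
estimator p = (1 + #{≥ observed})/(1 + R) (never zero; ties count as
exceedances, with a 1e-12 tolerance):

- *Differentiation*: region labels permuted over individuals, one
  permutation per replicate applied to all loci; one-tailed on the pooled
  statistic.
- *Phylogeographic signal* (Nst > Gst): haplotypes randomly relabelled,
  i.e. rows and columns of δ jointly permuted, independently per locus.
  Gst is invariant under this operation; only Nst is recomputed. The
  vectorized implementation permutes the frequency vectors against a fixed
  δ (algebraically identical) and is tested against a brute-force
  matrix-permutation oracle.

Both tests are vectorized across replicates (label-matrix × one-hot
haplotype indicators, then batched quadratic forms), which keeps 1000
permutations on a 30-individual locus around a millisecond.

## Kinship and isolation by distance

Pairwise kinship between haploid individuals is the Loiselle-type
estimator: per locus, num(i,j) = Σ_a (x_ia − p_a)(x_ja − p_a) +
Σ_a p_a(1 − p_a)/(n_l − 1) and den = Σ_a p_a(1 − p_a), combined across
loci by ratio of sums (loci where either individual is unscored drop out
of both sums for that pair). The small-sample correction makes the mean
over all distinct pairs exactly zero for a fully scored single-locus
dataset — an identity the tests assert to 1e-12 and the natural sanity
check for any implementation. Monomorphic loci are skipped with a warning.

Kinship is regressed by OLS on pairwise great-circle distance (haversine,
Earth radius 6371.0 km) or its natural log; under the log scale,
zero-distance pairs (same locality) are excluded with a warning. Slope
units are per km or per ln(km). Significance comes from a Mantel
permutation in which individuals' coordinate assignments are permuted
jointly (one permutation of the distance matrix's rows and columns per
replicate) — the permutation unit is the individual, not the locality
block. The default alternative is one-tailed negative, the
isolation-by-distance expectation; two-tailed is available. The pipeline
runs regions separately (within-south and within-north pairs;
cross-region pairs excluded) and skips species lacking coordinates,
logging the reason. Whether log-transforming distance improves fit is
assessed by a paired two-sided t-test on per-species r² values (zero
variance of differences returns t = 0, p = 1 with a warning).

## Comparative synthesis

Group summaries are unweighted means and sample SDs over species; group
contrasts use Welch's unequal-variance t-test with Satterthwaite degrees
of freedom, one-tailed in the direction of the stated hypothesis
(stronger structure in spermatophytes). Outlier exclusions are explicit
configuration entries — by default the one cpDNA row with near-complete
North/South allele segregation (Gst = 0.77) — and are never auto-detected.
Counts of significant tests use strict p < α on non-NA entries. The
packaged 28-species table stores published, 2-decimal values; synthesis
checks against it therefore use a ±0.01 tolerance, since the original
means were computed from unrounded inputs. The "both combined" partition
is synthesized from rows labelled `both` where present; published
combined-partition group means are not exactly recoverable from rounded
per-species values, so they are not used as fixture checks.

## Synthetic data

The generator draws genealogies under the structured coalescent with
exact exponential event times (no generation discretization): within a
deme holding k lineages, coalescence at rate k(k−1)/2/Ne per generation;
each lineage migrates at rate m to a uniformly chosen other deme (island)
or adjacent deme (1-D stepping stone). The cpDNA locus uses one genealogy
for all sites (optionally with a reduced effective size via
`cp_to_nuclear_ne_ratio`); each nuclear locus is independent. Mutations
are Poisson along branches; a substitution is a transition with
probability κ/(κ+2), else one of the two transversions — exactly the
two-parameter process the K2P estimator assumes. Individuals are haploid
throughout (bryophyte gametophytes are haploid; haplotypes are the
analysis unit). Datasets are bitwise reproducible from the seed.

With m = 0 and samples in several demes, lineages cannot meet; the
generator refuses unless `allow_incomplete_coalescence` is set, in which
case all surviving lineages are pooled into a single ancestral deme at
`isolation_cap_generations` and the coalescent completes there. This
models deep isolation with a panmictic ancestor while keeping node times
strictly increasing (force-joining at the cap would create zero-length
branches).

Scenario presets define the study conditions used by the tests and the
acceptance script:

- `panmixia`: one deme, N = 1000, n = 30, L = 500, μ = 5e-6 per site per
  generation (θ = 2NμL = 5, so datasets are essentially never
  monomorphic), alternating 50/50 region labels and scattered coordinates
  — the null for both the region permutation test and the Mantel test.
- `two_region_isolation`: two demes of 15, m = 0, cap 20N generations,
  μ = 2.5e-7, one cpDNA + two nuclear loci. Parameter logic: between-region
  divergence ≈ 2μL·(cap + N) ≈ 5.5 expected differences, while
  within-region θ = 0.25 keeps haplotype diversity low; since Gst ≈
  (1 − hS)/(1 + hS) under complete segregation, low within-region
  diversity is what pushes expected Gst to ≈ 0.65, comfortably above 0.5.
  (A 10N cap would force θ ≥ 0.5 to keep ≥ 5 expected differences, which
  lands expected Gst almost exactly at 0.5 — a coin flip.) Three loci are
  carried because the signal test permutes haplotype labels: with a single
  low-diversity locus (~3 haplotypes) the relabeling space has only a
  handful of states and p < 0.05 is unattainable; pooling loci, as the
  real multilocus datasets do, multiplies the permutation space.
- `island_migration`: two demes of 15, μ = 5e-7 (θ_deme = 0.5). The lower
  mutation rate is what lets migration tuning span Gst from ≈ 0 to ≈ 1:
  Gst is bounded above by within-deme homozygosity, so at high θ even
  complete isolation yields small Gst. Mean Gst over M = 2Nm ∈
  {0.1, 1, 10} is ≈ 0.44 / 0.16 / 0.02.
- `stepping_stone_ibd`: ten demes of 3 on a line at 45° N spanning
  ~1400 km (deme spacing 2° longitude), nearest-neighbour m = 5e-4
  (neighbour 2Nm = 1), μ = 5e-6. Kinship declines with distance; the IBD
  slope is negative in essentially all replicates and its per-km magnitude
  is comparable to empirical cpDNA slopes (~1e-5–1e-4 per km).

What the generator does *not* emulate: recombination within loci,
selection, demographic growth or bottlenecks beyond the isolation cap,
sequencing error, alignment error (simulated alignments are gapless, so
the cleaning stage is exercised mainly by constructed fixtures), and
uneven spatial sampling. Passing calibration and recovery tests on these
simulations therefore shows the estimators and tests behave correctly
under the model's own assumptions — not that real datasets meet those
assumptions.

## Problem sizes and numerical conventions

The test suite and acceptance script use 100–500 simulated datasets per
calibration/power check with 1000 permutations each; vectorized
permutation keeps the whole suite under a minute of compute. The type-I
error check accepts rejection rates inside the exact binomial 95 %
interval around α = 0.05; power checks assert the replicate fractions
stated above (joint Gst/signal ≥ 50 %, negative IBD slope ≥ 80 %, Mantel
null rejection ≤ 8 %). Permutation p-values live in (0, 1]; estimator
oracle agreement is asserted to 1e-12; ties in permutation counts use a
1e-12 tolerance. Seeds propagate through `numpy.random.SeedSequence`
spawning, so every analysis stage is reproducible and independent streams
never collide.

## The simulated two-group study

`full_sim_study` re-enacts the comparative design end to end: five
bryophyte-like species (spores carry both genomes; cpDNA and nDNA both see
2Nm = 8) against five spermatophyte-like species (pollen keeps nuclear
2Nm = 8; seeds move cpDNA poorly, modelled as an eightfold smaller
chloroplast Ne, i.e. cp 2Nm = 1), with μ = 4e-6 so the reduced-Ne
chloroplast remains polymorphic (θ_cp = 0.5). The expected — and
observed — pattern mirrors the empirical one: a significant
spermatophyte excess in cpDNA Gst, no group difference in nDNA.
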