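# Methods

`haplostat` implements the analysis chain used in haplotype-level
phylogeographic studies of non-recombining loci (an organelle intergenic
spacer and a nuclear ITS-like region are the motivating cases): within-
and among-population diversity, hierarchical structure, haplotype
networks, mismatch-based demography, and a coalescence-expectation test
that separates incomplete lineage sorting (ILS) from
hybridization/introgression. This note records the models, conventions
and numerical choices; nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Sequence handling

Input is one aligned FASTA per locus plus a TSV population map
(`sample_id population group lat_dd lon_dd`). Coordinates may be decimal
degrees or the degree–minute dialect of field tables (`23°31′N`,
`23'31''N`); a token-order parser reads numbers as degrees, minutes,
seconds regardless of the separator glyphs.

All statistics use **complete deletion**: any column containing a gap,
`N` or IUPAC ambiguity code in any sequence is removed for every
sequence. Haplotypes are equivalence classes of identical sequences over
the retained sites, so indels never distinguish haplotypes. Site classes
partition the alignment exactly: `monomorphic + polymorphic + excluded =
L` and `singleton + parsimony_informative = polymorphic`, with
parsimony-informative defined as ≥ 2 states each carried by ≥ 2
sequences (counted over the expanded sample, i.e. haplotypes weighted by
frequency).

## Diversity statistics

For n expanded sequences over L usable sites:

* k̄ — mean pairwise differences over all C(n,2) pairs, computed from
  per-site allele counts (identical to the naive O(n²L) double loop,
  which the tests run as an oracle).
* π = k̄ / L, with Nei's total sampling variance
  V(π) = (n+1)π / (3(n−1)L) + 2(n²+n+3)π² / (9n(n−1)).
* Haplotype diversity h = n(1 − Σp²)/(n−1) with Nei's single-sample
  heterozygosity variance. The "±" values printed by the report writer
  are the square roots of these variances; the exact variance dialect
  behind published tables is not always stated, so these are
  tolerance-bearing quantities, not exact reproduction targets.
* Tajima's D = (k̄ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
  constants; undefined (rendered "-") when n < 3, S = 0 or the variance
  term vanishes (note the variance coefficients are identically zero at
  n = 3, so D is undefined there even with polymorphism). Significance
  uses the beta-distribution approximation: D is assumed mean-0,
  variance-1 on [D_min, D_max] (the all-singleton and balanced-site
  limits) and two-sided tail areas are taken from the matching beta
  density; the report writer prints `*` (p < 0.05) and `**` (p < 0.01).

Statistics are always computed on expanded sequences (haplotype ×
frequency), never on the set of unique haplotypes.

## Distances, FST, AMOVA

Distances between haplotypes are plain Hamming counts over usable
sites. Because each site is a 0/1 indicator coordinate, the Hamming
count **is** the squared Euclidean distance between sequences, and
enters the molecular-variance sums of squares directly.

**Hudson's FST** is 1 − Hw/Hb, with Hw the unweighted average of the two
demes' mean pairwise differences over distinct within-deme pairs and Hb
the mean over all cross-deme pairs (the sequence-based
Hudson/Slatkin/Maddison estimator; Weir–Cockerham is deliberately not
implemented). Negative estimates are reported as computed. Two literal
copies of the same deme give exactly −1/(n−1), the known small-sample
offset of this estimator; identical monomorphic demes (Hb = 0) are
undefined and flagged. Group-level FST pools all sequences of a group by
default; averaging the population-pair FSTs is available behind a flag.

**AMOVA** solves the three-level variance components from sums of
squared deviations at the among-group / among-population-within-group /
within-population levels, with the unequal-sample-size coefficients of
the standard molecular-variance framework. Components are retained as
computed (negative values are not truncated) and percentages use the raw
total, so the three percentages always sum to 100. Φ_CT = σ_a/σ_total,
Φ_SC = σ_b/(σ_b+σ_c), Φ_ST = (σ_a+σ_b)/σ_total. Permutation p-values use
the three standard schemes — whole populations among groups (Φ_CT),
individuals among populations within groups (Φ_SC), individuals among
populations (Φ_ST) — with p = (#{perm ≥ obs}+1)/(n_perm+1); a flag marks
permutation spaces with fewer than 20 distinct states (e.g. few
populations), where p-values are uninformative.

**SAMOVA** maximises F_CT over partitions of populations into K
geographically contiguous groups. Contiguity is the Delaunay
triangulation of the population coordinates treated as planar (lon,
lat); degenerate geometry falls back to a nearest-neighbour chain, and
duplicate coordinates are deterministically jittered by 1e−6°. The
search runs `n_runs` independent simulated-annealing processes (default
100, the "annealing steps" convention of the original spatial-AMOVA
tool), each `n_iter` proposals (default 10 000) from a random contiguous
initial partition grown from K seeds. A proposal moves one boundary
population to an adjacent group and is rejected outright if it would
empty or disconnect its source group; improvements are always accepted,
deteriorations with probability exp(ΔF/T) under geometric cooling
(T₀ = 1.0, ×0.99 every 100 proposals — all four constants
config-exposed). Ties in the best F_CT break to the lexicographically
smallest canonical partition (groups as sorted index tuples, sorted by
smallest member), so results are reproducible bit-for-bit given the
seed. The reported F_CT is, by construction, exactly the Φ_CT of an
independent AMOVA on the winning partition, and on ≤ 7 populations the
annealer is validated against exhaustive enumeration of contiguous
partitions.

## Haplotype networks

The minimum-spanning network is the Kruskal MST over the haplotype
distance matrix (deterministic tie order: weight, then haplotype id)
plus every non-tree edge whose weight equals the maximum edge weight on
the tree path between its endpoints, flagged `alternative` — the
classic minimum-spanning-network convention in which all weight-tied
connections are displayed. Multi-step links are single weight-w edges;
the writer's `intermediate_steps` column (w − 1) supports renderers that
draw latent intermediate changes as filled nodes.

## Mismatch distributions and sudden expansion

The observed mismatch distribution is the normalised histogram of all
C(n,2) pairwise differences; its mean equals k̄ exactly. The
sudden-expansion model (scaled size θ₀ jumping to θ₁ at τ = 2ut
mutational units ago) has expected distribution

    F_i = F̂_i(θ₁) + exp(−τ(θ₁+1)/θ₁) Σ_{j≤i} τʲ/j! [F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)],

with F̂_i(θ) = θ^i/(θ+1)^{i+1}. Fitting is least squares on the observed
vector: a deterministic coarse grid (τ ∈ [0, 2·max class], 200 steps;
θ₀ ∈ [0, k̄]; θ₁ log-spaced in [k̄, 100k̄]) followed by iteration-capped
Nelder–Mead with θ₀ ≤ θ₁ enforced — reproducibility was preferred over
speed, and no parametric-bootstrap p-value for the SSD is computed. A
single-class observed vector short-circuits to τ = class index, θ₀ = 0,
flagged as a boundary solution. Harpending's raggedness
r = Σ(p_{i+1} − p_i)² is computed with a zero class padded at each end
of the support.

## Expected time to reciprocal monophyly and the ILS verdict

After a split, a neutral locus is expected to reach reciprocal monophyly
in about 1.665 Ne generations (haploid organelle) or 1.665 · 2Ne
generations (nuclear). With θ = 4Ne·μ and μ = U·G (U the per-locus
yearly mutation rate, G the generation time), the calendar-time windows
are T = 1.665 θ/(4U) and 1.665 θ/(2U) — G cancels. U is the
endpoint-wise geometric mean across loci of per-site rate × locus
length. A window over a set of θ estimates and a U interval pairs the
smallest θ with the fastest rate (lower endpoint) and the largest θ with
the slowest rate (upper endpoint); this pairing is the convention that
reproduces published window endpoints from their stated inputs, and a 1%
tolerance is attached because the effective locus lengths entering U are
not always stated to the site. ITS length defaults to the full 628-site
alignment; the convention that excludes the conserved rRNA segments is
config-expressible.

The verdict compares the monophyly window with an independently
estimated divergence window: `overlap` means monophyly is attainable
within the divergence time (ILS alone can explain shared polymorphism);
`expected_exceeds` (window entirely above the divergence window) means
lineage sorting is expected to be incomplete and paraphyly persists.
Isolation-with-migration point estimates are consumed as config inputs
(the MCMC itself is out of scope); any migration HPD whose lower bound
exceeds the threshold (default 0) additionally implicates
hybridization/introgression. Conversions Ne = θ/(4UG) and
2Nem = m·θ/2 are provided; Ne requires a user-supplied generation time.

## Synthetic data generator

The generator is a structured coalescent with migration, an optional
ancestral merge (a forward-time split), and optional stepwise size
change, plus infinite-sites mutation on a finite length so that Hamming
distance equals mutation count (matching the network and diversity
framing). Scaling follows the ms convention: a pair of lineages in a
deme of relative size σ coalesces at rate 1/σ, migration rates are
per-lineage in coalescent time, and mutations fall at rate θ/2 per
lineage-time, giving E[k̄] = θ and E[S] = θ·a₁(n) under panmixia —
properties the tests verify against both theory and an independent
coalescent implementation (msprime). Mutations take unique sites
(redrawn up to 10 times, then an error, if a draw exceeds the locus
length); each mutated site flips to a uniformly chosen different base.
An organelle-style locus with inheritance scaling c < 1 has all deme
sizes multiplied by c (faster coalescence, expected diversity c·θ); no
cytonuclear size ratio is assumed by default (c = 1).

The symmetric two-deme helper takes Nm (migrants) and sets per-lineage
rates Nm/2 each way, which makes the coalescent-time ratio behind
Hudson's FST equal 1/(1 + 2Nm).

**Study-design fixture.** `paper_mimic_fixture` emulates the motivating
sampling design: 14 populations in 4 mountain-range groups, per-
population sample sizes 1–9 (n = 70), real coordinates, two loci of 585
and 628 sites, with the three-population Yushan-like group split off
1.2 coalescent units ago and nearly isolated (pairwise per-lineage
migration 0.001 across the split vs 15 within the connected remainder;
deme size 1/14, ancestral size 0.5, θ = 6 per locus). The defaults come
from island-model arithmetic: within the 11-deme connected network a
pair of lineages coalesces in about the network's total size
(11/14 ≈ 0.79 time units, k̄ ≈ 4.7 differences), across the split in
about split time + ancestral size (1.7 units, k̄ ≈ 10), giving pooled
π ≈ 0.011 on 585 sites and an among-group fixation index near 0.6 for
the true two-group partition, the conditions the design emulates;
realized values across seeds are π ≈ 0.005–0.018 and F_CT ≈ 0.34–0.86.
What the fixture does *not* emulate: the real data's higher diversity
inside the isolated group than outside it, mutation-rate heterogeneity
among sites, indels and ambiguity codes, and any selection or
recombination — so passing tests validate the estimators under neutral,
infinite-sites conditions, not those data features.

**Expansion fixture.** A single deme whose size drops by the expansion
factor at `t_expansion` (backwards in time); the truth record carries
τ = θ·t. Mismatch-based τ recovery is intrinsically genealogy-noise
limited: the informative regime is a *recent* expansion (expansion time
small relative to the current coalescent timescale, so many lineages
survive to the expansion and deep branches are many). The parameter-
recovery test therefore uses factor 100 at t = 0.15 with θ = 60 and
n = 80 on 2 000 sites (median |τ̂ − τ|/τ ≈ 10%); under an older/weaker
signal (e.g. τ = 3 from θ = 10, t = 0.3, n = 30) the median error
roughly doubles — a property of the statistic, not of the optimiser.

## Problem sizes used in the test suite

Stochastic validation uses 300–1 000 replicates per expectation check
(neutral E[S]/E[k̄], island-model FST at Nm ∈ {0.1, 1, 10}, expansion
Tajima's D, τ recovery, mismatch unimodality), 20 seeded repetitions for
SAMOVA-vs-exhaustive and isolated-group recovery, and reduced annealing
budgets (20–100 runs × 300–2 000 iterations) on the small problems where
that demonstrably attains the exhaustive optimum. All seeds are fixed;
every stochastic result in the package is a pure function of (inputs,
config, seed).

## Known limitations

* No recombination, selection, or sequencing-error model in the
  generator; no finite-sites substitution models anywhere (distances are
  mutation counts by design).
* Tajima's D significance uses the beta approximation only; no
  coalescent-simulation null.
* The sampling variances behind π ± and h ± follow Nei; other programs'
  "±" columns may use different dialects.
* Hudson's FST is the only FST estimator; its small-sample offset
  (−1/(n−1) for undifferentiated demes) is inherent to the pair-mean
  definition.
* SAMOVA is a stochastic search; global optimality is only guaranteed
  where exhaustive enumeration is feasible (tests cover ≤ 7
  populations).
* The ILS verdict is interval arithmetic on point/interval summaries; it
  propagates no posterior uncertainty beyond the supplied HPD bounds.
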