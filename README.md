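# haplostat

Haplotype-level phylogeography toolkit for aligned, non-recombining
loci (organelle spacers, nuclear ITS and the like) sampled across
structured populations.

Given one aligned FASTA per locus and a population map
(sample → population → geographic group, with coordinates), the package
computes the full analysis surface such studies report:

* **Diversity** — haplotype collapsing, site classification
  (polymorphic / parsimony-informative), nucleotide diversity
  π = k̄/L with Nei's sampling variance, haplotype diversity
  h = n(1−Σp²)/(n−1), and Tajima's
  D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)) with beta-approximation
  significance.
* **Structure** — pairwise Hudson FST (1 − Hw/Hb from sequence
  differences), three-level AMOVA (variance components σ_a, σ_b, σ_c
  and Φ_CT, Φ_SC, Φ_ST with permutation p-values), and SAMOVA:
  simulated-annealing search for the K-group partition of
  geographically contiguous populations maximising F_CT.
* **Networks** — minimum-spanning haplotype networks over mutational
  steps, with all weight-tied alternative connections flagged.
* **Demography** — mismatch distributions and least-squares fits of the
  Rogers–Harpending sudden-expansion model (τ, θ₀, θ₁), plus
  Harpending's raggedness.
* **Coalescence calculus** — expected time to reciprocal monophyly
  T = 1.665·θ/(4U) (organelle) or 1.665·θ/(2U) (nuclear), with U the
  geometric mean across loci of per-locus yearly mutation rates, and an
  interval-arithmetic verdict separating incomplete lineage sorting
  from hybridization/introgression.
* **Simulation** — a structured-coalescent generator (migration,
  splits, size changes; infinite-sites mutation so Hamming distance =
  mutation count) producing alignments + population maps with known
  truth, including a 14-population / 4-group study-design fixture.

## Worked example

Simulate a study-design dataset and run the whole pipeline:

```sh
haplostat simulate --seed 7 --outdir demo
haplostat stats demo/cp_like.fasta demo/popmap.tsv --scope all
```

```
unit  n   H   S   pi        pi_se     hd        hd_se     tajima_d   significance
all   70  18  31  0.011991  0.006319  0.911387  0.014972  0.288068
```

70 sequences collapse to 18 haplotypes with 31 segregating sites;
pooled nucleotide diversity is ≈ 0.012 differences per site and
haplotype diversity ≈ 0.91. The SAMOVA scan
(`haplostat samova demo/cp_like.fasta demo/popmap.tsv`) recovers the
isolated mountain-range group at K = 2:

```
K  grouping                                                  f_ct      p
2  (AA, CB, CK, CY, CS, CN, CH, SS, SL, SB, SC)(YT, YY, YP)  0.758966  0.010
3  (AA, CB, CK, CY, CS, CN, CH, SS, SL, SB)(SC)(YT, YY, YP)  0.750528  0.005
```

i.e. ≈ 76% of molecular variance lies between the isolated group and
the rest — the generator's ground truth. The monophyly calculus from a
config of published-style inputs (θ ∈ {30.81, 95.43}; per-site rates
1.0–3.0 × 10⁻⁹ over 585 sites and 5.0–7.8 × 10⁻⁹ over 628 sites):

```sh
haplostat monophyly --config mono.yaml
```

```json
{"U_per_locus_per_year": [1.355e-06, 2.932e-06],
 "organelle": {"t_low_years": 4374015, "t_high_years": 29308690},
 "nuclear":   {"t_low_years": 8748030, "t_high_years": 58617381}}
```

The organelle window (≈ 4.4–29.3 MYA) overlaps a divergence window of
2.895–8.722 MYA, so lineage sorting alone can explain shared organelle
polymorphism; the nuclear window (≈ 8.7–58.6 MYA) lies entirely above
1.879–2.909 MYA, so nuclear monophyly is not expected yet and observed
paraphyly needs no introgression to explain — though non-zero migration
estimates would additionally implicate it. `haplostat run --config
cfg.yaml` executes every stage and writes the per-population statistics
table, SAMOVA scan, FST matrices, network edge/node lists, mismatch fits
and the verdict JSON, plus a manifest with the seed and config hash.

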