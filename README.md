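# snpnet

Genotype-superset networks for case-control risk classification.

Conventional SNP association studies rank markers one locus (or one
haplotype) at a time.  `snpnet` implements a combinatorial alternative
for small multi-SNP panels: each individual's genotypes across all M
markers are concatenated into a *genotype superset* (e.g.
`12 22 11 22 11`, alleles coded 1 = wild / 2 = variant), and the cohort
becomes a network with one super-node per disease group and one node per
observed superset, joined by edges weighted by carrier counts.  Supersets
observed in only one group are *group-specific*; the rest are shared.
The package is aimed at genetic-epidemiology analyses of candidate-gene
panels (a handful of SNPs, hundreds of individuals) where genotype
combinations, not single alleles, may separate cases from controls.

On top of the network it provides:

* **Knockout ranking** — remove one SNP at a time from every superset;
  supersets differing only there collapse.  The SNP whose omission
  leaves the fewest case-specific supersets (rank 1) is the strongest
  risk candidate, with a Yates chi-square on the [full vs omitted] ×
  [case-specific, control-specific] node counts for restructuring
  significance.
* **Shuffle nulls** — genotype-preserving (Type 1) and allele-preserving
  (Type 2) within-group permutations that keep every single-SNP
  case-control statistic fixed while destroying cross-SNP combinations;
  *rank conservation* is the % of replicates in which a SNP re-occupies
  its original knockout rank.
* **Segregation curve** — shared (case ∩ control) superset count as a
  function of SNP-subset size on large panels; beyond a threshold size
  every individual's combination is group-unique.
* **Association statistics** — Yates-corrected chi-square, odds ratios
  with Woolf 95% CIs, one-vs-rest haplotype ORs (>3% frequency filter),
  two-locus haplotype frequencies by EM from unphased genotypes, and
  pairwise LD (D, D′, r²).
* **Synthetic cohorts** — seeded Hardy–Weinberg generators with planted
  risk SNPs and LD pairs (`acs-like`, `oral-like`, `panel-like`
  presets), so every stage is testable without any data download.

## Worked example

Generate a two-group cohort (91 cases / 86 controls, 5 SNPs, risk SNP
planted at SNP4 with minor-allele frequency 0.40 vs 0.03) and run the
full analysis:

```bash
snpnet synth --preset acs-like --seed 11 --out g.tsv
snpnet network --genotypes g.tsv
```

```
P=177 individuals, M=5 markers, N=38 supersets
  case: 19
  control: 10
  case+control: 9
```

Of the 38 observed supersets (out of 3⁵ = 243 possible), 19 occur only
in cases, 10 only in controls, and 9 in both.  The knockout scan:

```bash
snpnet knockout --genotypes g.tsv --case case --control control
```

```
marker  n_nodes  case_specific_nodes  control_specific_nodes  ...  rank_case_specific_nodes
  SNP1       22                   11                       4  ...                         2
  SNP2       24                   12                       6  ...                         3
  SNP3       33                   16                       8  ...                         4
  SNP4       20                    5                       5  ...                         1
  SNP5       33                   16                       8  ...                         5
ranking (case_specific_nodes): SNP4 > SNP1 > SNP2 > SNP3 > SNP5
```

Omitting SNP4 collapses the case-specific supersets from 19 to 5 — far
more than any other omission — so SNP4 is flagged as the risk marker
(rank 1), recovering the planted effect.  Its rank is stable under the
genotype-preserving null:

```bash
snpnet simulate rank-conservation --genotypes g.tsv --case case \
    --control control --method type1 --reps 200 --seed 17
```

```
 rank marker  conservation_pct
    1   SNP4             100.0
    2   SNP1              45.0
    3   SNP2              23.0
    4   SNP3              25.5
    5   SNP5              23.0
```

SNP4 holds rank 1 in 100% of 200 shuffled replicates, while the
uninformative background markers churn near the random baseline.  The
planted LD pair is recovered too:

```bash
snpnet assoc --genotypes g.tsv --case case --control control --ld 2 4
```

```
LD SNP3 x SNP5: D=0.0982 D'=0.9450 r2=0.8471 (EM 7 iterations)
```

(the generating value is r² = 0.70; a 177-individual cohort estimates it
with substantial sampling noise).

The same workflow is available as library calls: `parse_dataset` /
`build_superset_table` (snpnet.geno_core), `build_network` /
`partition_nodes` / `write_pajek` (snpnet.network), `knockout_scan` /
`rank_markers` (snpnet.knockout), `rank_conservation` /
`segregation_curve` (snpnet.simulation), and the statistics in
snpnet.association.

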