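# Methods

## The model

`snpnet` analyses case-control (or multi-stage) cohorts genotyped at M
biallelic SNPs through the *genotype superset*: the ordered string of an
individual's M genotype calls, e.g. `12 22 11 22 11`, with alleles coded
`1` (wild) / `2` (variant) and heterozygotes canonicalized (`21` ≡ `12`).
Over M markers there are 3^M possible supersets; a cohort of P
individuals realizes N ≤ min(P, 3^M) of them.

The network **R** has k *super-nodes*, one per disease group, and one
node per observed superset.  A node is joined to the super-node of every
group in which its superset occurs, with edge weight w equal to the
number of carriers in that group (1 ≤ w ≤ P; weights into a super-node
sum to the group size; the grand total of weights is P).  Nodes touching
exactly one super-node are *group-specific*; the rest are *shared*.  Two
summary fractions are used throughout: the node-basis specific fraction
(group-specific nodes / N) and the individuals-basis specific fraction
(weight carried by group-specific nodes / P).

## Knockout ranking

Omitting marker j deletes position j from every superset; supersets that
differed only there collapse, so N′ ≤ N while group sizes are conserved.
Omission commutes across markers.  For each of the M single-marker
omissions the scan records the membership-class counts and specific
fractions of the rebuilt network.  Markers are ranked ascending by the
focal-group-specific node count remaining after their own omission
(criterion `case_specific_nodes`), or by the focal/reference specific
ratio (`case_control_ratio`); rank 1 — the largest collapse of
focal-specific variation — marks the strongest risk candidate.  Ties
keep marker input order.  When the reference count is zero under the
ratio criterion, 0.5 is added to both counts (a continuity rule that
keeps the ranking total).

Restructuring significance is assessed by a Yates-corrected chi-square
on the 2×2 table [full vs omitted network] × [focal-specific,
reference-specific node counts].  This is the simplest table consistent
with a "chi-square on one-SNP omission"; it is an interpretation, since
a node-count table is not the only possible contrast, and it is flagged
as such in the report.

## Shuffle nulls and rank conservation

Two permutation nulls probe the ranking's robustness:

* **Type 1 (genotype-preserving)** — each marker's column of calls is
  permuted across the individuals of each group.  Per-marker genotype
  counts are conserved exactly, within every group and pooled.
* **Type 2 (allele-preserving)** — per marker and group, the 2n alleles
  are pooled, permuted and re-paired into genotypes.  Allele counts are
  conserved; heterozygote/homozygote counts may change.

Both act *within* groups, so every single-marker case-control statistic
(genotype- or allele-level chi-square) is exactly unchanged under the
respective null — the shuffles destroy only the combinatorial pairing of
genotypes across SNPs within an individual, which is precisely the
structure the superset network exploits and conventional single-SNP
tests ignore.  A pooled (across-group) permutation would instead destroy
the per-SNP marginal associations; under such a null the post-omission
specific counts of all markers differ only marginally (we measured
expected gaps below one node on study-sized cohorts) and rank
conservation collapses to the 1/M random baseline, which cannot produce
the near-total rank-1 conservation the method is designed to detect.

*Rank conservation* re-runs the scan on each shuffled replicate and
reports, per original rank, the percentage of replicates in which the
original marker re-occupies exactly that rank.  Replicate r uses an
independent generator seeded `seed + r` (kept below 2³¹), so runs are
reproducible and order-independent.  The package default is 1000
replicates; the test-suite and acceptance runs use 200, which bounds the
Monte-Carlo standard error of a conservation percentage near 100% well
under the 5-point margin the checks allow.

## Segregation curve

For subset sizes s (default 5–250), s marker columns are drawn uniformly
without replacement, supersets are rebuilt for two groups, and the
number of supersets observed in both is recorded (mean ± sd over
replicates).  As s grows, supersets individuate and the shared count
falls to zero and stays there — beyond that size every individual's
combination is group-unique, which bounds the number of SNPs a cohort of
a given size can support before case/control "common" structure
vanishes entirely.

## Association statistics

* **Yates chi-square**: χ² = Σ (max(|O−E|−0.5, 0))²/E, df = 1; the
  correction is floored so it never overshoots.  Undefined (error) when
  a margin is zero.
* **Odds ratio, Woolf CI**: OR = (a/b)/(c/d), 95% CI =
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  A zero cell triggers the
  Haldane–Anscombe +0.5 on all four cells (flagged in the result) for
  the OR/CI only — never for the chi-square.
* **Haplotype risk table**: haplotypes at frequency > 3% in either group
  are tested one-vs-rest (this haplotype vs all others × case vs
  control), oriented as odds of the haplotype in cases over controls.
* **Two-locus EM**: under Hardy–Weinberg random mating only the double
  heterozygote is phase-ambiguous; the E-step splits it between cis and
  trans in proportion to f11·f22 vs f12·f21, the M-step re-estimates the
  four haplotype frequencies.  Convergence at max |Δf| < 1e-8 or 1000
  iterations from a uniform start; the log-likelihood is asserted
  non-decreasing at every step.  At the optimum the allele frequencies
  equal the sample frequencies, which reduces the independent check to a
  one-dimensional grid search over D (step 1e-3).
* **LD**: D = p11 − pA·pB, r² = D²/(pA(1−pA)pB(1−pB)), D′ = D/Dmax with
  Dmax = min(pA(1−pB), (1−pA)pB) for D > 0 and min(pA·pB, (1−pA)(1−pB))
  for D < 0.  r² and |D′| are invariant under allele relabeling.

## Synthetic cohorts

No per-individual cohort from this class of study is publicly deposited,
so the generator produces cohorts with the statistical structure the
method assumes: genotypes drawn per group under Hardy–Weinberg from
group-specific minor-allele frequencies; an optional LD pair drawn as
two haplotypes per individual from an explicit four-haplotype
distribution; optional uniform missingness, which the parser removes
(matching the analysis rule of dropping incomplete individuals).

Presets (frozen defaults):

* `acs-like` — 91 cases / 86 controls, 5 SNPs.  SNP4 is the single
  planted risk marker, minor-allele frequency 0.40 in cases vs 0.03 in
  controls — the allele-frequency contrast observed at the strongest
  locus of an ACS cohort of exactly this size.  All other markers are
  exchangeable background with identical frequencies in the two groups
  (0.18, 0.12, 0.15, 0.15): the planted marker is then the only source
  of case-control signal, which is the cleanest realization of "one
  planted ground-truth risk SNP" for validating the knockout ranking.
  SNP3 and SNP5 form an LD pair at r² = 0.70 (shared maf 0.15).  The
  pair deliberately excludes the risk marker: a marker cannot both carry
  a group-specific allele frequency and be generated from a single
  haplotype distribution shared by the groups.
* `oral-like` — three groups (369 controls / 219 leukoplakia / 298
  cancers), 5 unlinked SNPs, with an elevated cancer-group frequency at
  SNP2.
* `panel-like` — 1804 independent SNPs × 635 individuals (318/317
  case/control split; the split is not published, so an even split is
  used), per-marker maf uniform on [0.05, 0.5], identical in both groups
  (a null panel: the segregation curve is a pure individuation effect).

What the generator does **not** emulate: genotyping error beyond uniform
missingness, population structure/relatedness, departures from
Hardy–Weinberg within group, LD blocks longer than one pair, and
covariates (age/sex).  Passing tests therefore demonstrate the machinery
and its null calibration on idealized cohorts, not robustness of the
biological conclusions to those real-data features.

## Numerical and design choices

* Superset strings are space-separated calls in marker column order and
  are the node key everywhere; node order is lexicographic, making every
  report and the Pajek export byte-stable.
* Pajek vertices are 1-based with super-nodes at ids 1..k in declared
  group order, then nodes; edges are undirected with integer weights;
  zero-count (group, superset) pairs get no edge.
* Missing-data codes `NA`, `00`, `--` and the empty cell all drop the
  individual; there is no imputation, phasing, or multi-allelic support.
* Problem sizes in the shipped checks: 200 shuffle replicates on the
  91/86 cohort; 200 replicates × 11 subset sizes on the 1804×635 panel;
  property tests on cohorts up to M = 4, P = 30 against brute-force
  string-collapse oracles.

## Known limitations

* The restructuring chi-square's 2×2 construction is an interpretation
  (node counts, not individual counts); reported p-values may differ
  from analyses that contrast population fractions.
* Printed summary tables from the motivating study contain internal
  inconsistencies (allele rows inconsistent with genotype rows; a
  published haplotype OR of 39.31 where the closed-form value on the
  printed counts is 40.31).  The package always reports closed-form
  values computed from its inputs.
* Covariate-adjusted (logistic) odds ratios are out of scope: they
  require per-individual covariates that are not available.
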