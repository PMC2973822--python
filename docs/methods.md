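# Methods

This note records the models behind each module, the defaults and why,
the numerical choices, and what the synthetic data do and do not show.

## Data model

A locus registry fixes the ordered set of typed markers; registry size is
data-driven (the chimpanzee-style default uses 14 presence/absence
markers for 13 genes — the fused 3DL1/2 region carries two markers, kept
distinct by default because collapsing them changes diversity counts).
Genotypes are complete presence/absence matrices; missing cells are
rejected at load rather than imputed, because every downstream statistic
(distinct-genotype identity, Hamming differences, EM pair likelihoods)
assumes complete typing. A locus is "present" when at least one copy
exists on either chromosome; copy number is not modelled. Residue
positions (76/80) are 1-based in the mature protein; any leader-peptide
offset must be applied by the caller (`--leader-offset` on the CLI).

## Synthetic data

The generators reproduce the statistical structure the analyses assume,
not sequences:

- **Chimpanzee-style pools.** Haplotypes arise from independent presence
  of recombination units confined to the centromeric interval; pairs in
  absolute linkage are merged into single units before enumeration (the
  merged unit's probability is the arithmetic mean of its members' — a
  single probability must govern a co-segregating block). Defaults are
  anchored to the study panel's printed haplotype statistics: the
  2DS4-carrying unit at 8% of haplotypes and the 2DL5 unit at 52%, so
  0.48 × 0.92 ≈ 44% of haplotypes carry neither 2DS4 nor 2DL5; the other
  units sit at the 0.6–0.9 presence probabilities typical of the
  high-frequency pairs.
- **Human-style pools.** Haplotypes are centromeric × telomeric motif
  combinations with product frequencies; default motifs follow the
  canonical A/B-haplotype structure at European-ancestry-like frequencies
  (2DS4 on ~55% of haplotypes).
- Both pool modes admit closed forms, so `simulate_haplotype_pool`
  returns the **exact** distribution (identical vectors merged) rather
  than a finite sample; the `seed` argument is accepted for interface
  symmetry only. Exactness matters because the LD formulas are defined on
  the distribution itself.
- **Genotypes.** Hardy-Weinberg pairing: two haplotypes drawn i.i.d. from
  the pool, OR-ed. Nothing in the emulated panels suggests deviation from
  random pairing, and the EM model assumes it.
- **Frequency tables.** Per-key uniform draws within ranges typical of
  worldwide surveys (2DL1 0.90–1.00 — nearly universal; 2DL2 0.30–0.92
  and C2 0.15–0.80 — the most variable; 2DL3 0.75–1.00; C1 0.55–1.00;
  B46 0.08–0.28 confined to East-Asian-group populations). 33 populations
  in 8 regional groups by default.
- **Tip states.** A root state is propagated down the tree with
  substitution events placed on named edges. Edges are identified by the
  child's tip-set signature (or tip label), since Newick has no canonical
  edge labels; two events on one edge are rejected as contradictory, and
  an event whose source state disagrees with the propagated state is an
  error rather than silently rewritten.

What passing on synthetic data does **not** show: real panels contain
relatives, typing error and genuinely missing cells; real haplotype pools
are not exactly unit-independent; real population frequencies covary
geographically rather than being uniform draws. Results on real data
depend on those features; the tests establish correctness of the
computations, not robustness to data pathologies the loaders reject.

## Diversity

Rarefaction draws n individuals **without replacement** per replicate
(default n = 26, matching the unrelated-subset size used for
cross-species comparison; 5,000 replicates) — subsampling to a common
size is the point, and with-replacement bootstrap is available behind a
flag. The 95% CI is percentile-based (2.5–97.5); with n equal to the
panel size every replicate equals the full-panel count, so the summary is
deterministic. The pairwise difference is the mean Hamming distance over
all unordered pairs (no self-pairs, loci equally weighted); the SE comes
from resampling loci columns with replacement (10,000 replicates),
treating each locus as a single biallelic marker. Column-degenerate
matrices therefore give SE 0.

## LD and association ratios

Pairing frequency compares Σf(both present) + Σf(both absent) with
pA·pB + (1−pA)(1−pB). The Fisher test needs integer counts: frequencies
are scaled by a caller-supplied chromosome count (2N), rounded by largest
remainder so cells stay consistent with the total. Two-tailed means
summing point probabilities ≤ the observed table's (the usual
convention); significance threshold defaults to 0.001, configurable, and
no multiple-testing correction is applied by default (per-pair
significance at a fixed threshold is the convention here; Bonferroni is a
flag away in the caller's hands since the pair list is theirs). A zero
marginal yields p = 1.0 with a logged warning. Association ratios use
conditional presence frequencies P(g | ref⁺)/P(g | ref⁻), which is the
natural reading of "normalized for the unequal mass of ref⁺ and ref⁻
haplotypes"; declared absolute-linkage constraints substitute the
partner's presence vector and flag the output (the parenthesized-ratio
convention). Ratio = ∞ ("AL") when the denominator alone is zero, NaN
when both are.

## EM haplotype frequencies

Candidates default to every vector ≤ some observed genotype (any such
vector can serve as half of a compatible pair, with the genotype itself
as partner); the empty, framework-only haplotype is therefore always
legal. A cap (default 4096) guards against exponential blow-up on panels
where many loci are jointly present — restrict loci or supply candidates
in that case. The likelihood is multinomial over genotypes with
P(g) = Σ_{h₁∨h₂=g} f(h₁)f(h₂)(2−δ_{h₁h₂}); the M-step sets each frequency
to half its expected dosage. Initialization is uniform (deterministic);
`seed` enables a Dirichlet restart for plateau escape. Convergence is
max |Δf| < 1e-8 within 10,000 iterations; non-convergence is reported,
not raised — near-boundary solutions approach their limit geometrically
slowly while the estimates are already stable to far better than
sampling error. OR-genotypes can leave frequency combinations
non-identifiable; after fitting, the curvature of the log-likelihood is
probed along each simplex direction (central second difference,
ε = 1e-4) and directions with |curvature| < 1e-6 are reported as flat.
This module is a self-contained estimator validated by simulation
(total-variation error < 0.05 at n = 500 for pools of ≤ 6 haplotypes,
averaged over 20 seeds); it handles unrelated individuals only — no
pedigree-aware phasing.

## Epitopes and the co-occurrence test

The rule table is exact: Bw4 ⟺ I80/T80 (V76 on that background flags the
conflict — such variants perturb Bw4 binding while creating neither C1
nor C2); C1 ⟺ V76∧N80; C2 ⟺ V76∧K80; anything else none. Unknown
residues degrade to none with a flag and are excluded from frequency
denominators. The co-occurrence test is the one-sided upper tail
P(X ≥ k), X ~ Binomial(n, background) — directional because the
hypothesis is that V76-creating substitutions *always* land on N80; with
all events on the background it reduces to backgroundⁿ (0.67⁸ ≈ 0.041
for the canonical inputs). The background fraction defaults to 1 − the
I80/T80 fraction of a supplied allotype list and can be overridden
numerically (0.67 for the canonical rounded figure).

## Parsimony change counting

Unit-cost Sankoff rather than Fitch, so polytomies and alphabets > 2 need
no special-casing. Direction attribution differs between
most-parsimonious reconstructions (the ACCTRAN/DELTRAN ambiguity), so
per-transition counts are [min, max] ranges over all MPRs. The ranges are
exact at any tree size: for each ordered transition the recursion is
re-run on lexicographic (total changes, ± transition count) costs, which
finds the extreme count among cost-optimal reconstructions without
enumeration. The single reported reconstruction breaks ties toward the
parent's state (late, DELTRAN-style changes). A supplied root state must
be achievable by an MPR — it is reported as incompatible, never forced at
extra cost; note that under unit costs a state absent from the tips never
appears in any MPR, so such a root constraint always errors. Minimum
counts are lower-bound statements ("at least k events"); this module
deliberately does not reproduce likelihood-based ancestral posteriors —
no branch lengths, no codon models.

## ANDI

Phenotype (carrier) frequencies enter throughout; a helper converts
allele to carrier frequency under HWE (PF = 1−(1−af)²) for tables built
from allele-frequency sources. B*46 terms apply only to populations
flagged as B*46-carrying — a per-population flag, not a hard-coded region
list. Summaries report both granularities (33 populations and 8 regional
groups) since range statements can aggregate either way; the group
statistic is the median of each group's population values. The HWE
maximum treats C1/C2 as a biallelic epitope system at HLA-C (every allele
carries exactly one epitope): C1 = 1−(1−c)², C2 = 1−c², and the C-terms
are maximized over c ∈ [0,1] by bounded scalar optimization (xatol 1e-10,
endpoints checked explicitly since the objective is quadratic in c);
B*46, not being an HLA-C allele, is held fixed. Pearson correlations use
the standard product-moment formula with an optional leave-one-out report
to surface single-population outliers.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; no global RNG state.
The validation suite uses the study-scale conditions directly where they
are cheap (5,000 rarefaction replicates, 10,000 bootstrap replicates,
n = 500 EM panels over 20 seeds, all 46k Fisher tables of total ≤ 30,
100 random trees of ≤ 20 tips against a vectorized exhaustive-labeling
oracle) — the whole suite runs in well under a minute.

## Known limitations

- The published 33-population KIR/HLA frequency compilation is available
  only in figure form; the ANDI survey reproduction therefore runs on
  synthetic tables unless the user transcribes the source values to TSV.
- EM assumes unrelated individuals and random pairing; panels of
  relatives must be masked to their unrelated subset.
- Association ratios and pairing frequencies are defined on haplotype
  distributions, not genotype data; haplotypes must be estimated first.
- Parsimony counts are lower bounds and share parsimony's general bias
  under high rates or strongly unequal branch lengths.
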