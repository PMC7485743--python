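# Methods

This note documents the models and numerical choices behind each stage
of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Selection scan (Ka/Ks)

Per ortholog pair, synonymous (S) and nonsynonymous (N) site counts
follow Nei–Gojobori (1986) counting: each of a codon's nine
single-nucleotide mutants contributes 1/3 of a synonymous site if it
preserves the amino acid, otherwise 1/3 of a nonsynonymous site;
mutants that create stop codons count as nonsynonymous.  Sites are
summed per sequence and averaged between the two sequences.
Substitutions (Sd, Nd) between differing codons are averaged over all
orderings of the differing positions, excluding paths through stop
codons (all paths are kept if every one is blocked); Sd + Nd always
equals the number of differing positions.  Codons containing gaps,
ambiguity codes or stops in either sequence are excluded.

Observed proportions ps = Sd/S and pn = Nd/N are corrected for
multiple hits with the one-parameter Jukes–Cantor formula
d = −(3/4)·ln(1 − (4/3)·p), undefined at p ≥ 3/4 (the gene is flagged
`saturated` and excluded from FDR adjustment).  ω = Ka/Ks is defined
only when Ks > 0 (`undefined_ratio` otherwise).

Significance uses Fisher's exact test on the integer table
[[round(Nd), round(N − Nd)], [round(Sd), round(S − Sd)]].  The
one-sided `greater` tail (excess nonsynonymous change) is the primary
p-value; the opposite tail is adjusted separately so that purifying
selection (ω < 1) can be called symmetrically.  Both tails are
BH-adjusted across genes.  Classification: `positive` when ω > 1,
FDR < 0.05 (configurable) and no filter flag; `purifying` when ω < 1
and the opposite-tail FDR clears the same threshold; `none` otherwise.
Filters: `short_alignment` when fewer than 100 compared bp
(configurable), `low_coverage` when compared bp / alignment columns
< 0.8.  Coverage is defined on compared codons because the input
format carries no other notion of aligned fraction.

This NG86 + Jukes–Cantor estimator is a deliberate, documented
substitution for model-averaged maximum-likelihood Ka/Ks estimation:
it preserves the scan's full contract (ω, Fisher p, FDR, filters) and
is exactly checkable against enumeration oracles.  It carries NG86's
known mild downward bias in ω at high divergence (no
transition/transversion weighting, no codon-frequency model); the
parameter-recovery tests bound this bias within ±20% for
ω ∈ {0.1, 1, 2} at divergence 0.2.

## Statistical primitives

All tests are implemented in `longbat.stats`:

* **Wilcoxon signed-rank** — zeros dropped before ranking, mid-ranks of
  |d|, statistic W⁺.  For n ≤ 25 the null distribution is obtained by
  dynamic programming over doubled ranks, equivalent to enumerating
  all 2ⁿ sign assignments (ties included); otherwise a normal
  approximation with tie correction and 0.5 continuity correction.
* **Wilcoxon rank-sum** — exact distribution of the rank sum via DP
  over rank subsets when n_x + n_y ≤ 20 with no ties, otherwise normal
  approximation with tie correction.  Fully tied samples give p = 1.
* **Fisher exact / hypergeometric** — log-gamma probabilities, exact
  tail sums; the two-sided p sums tables with probability ≤ observed
  (relative tolerance 1e-9).
* **Benjamini–Hochberg** — step-up q_(i) = min monotone of p_(i)·m/i,
  returned in input order.
* **Two-sample KS** — sup-distance of ECDFs, asymptotic p from the
  Kolmogorov series Q(t) = 2·Σ(−1)^(k−1)·e^(−2k²t²) at
  t = √(n_x n_y/(n_x+n_y))·D.
* **Pearson χ² (2×2)** — no continuity correction, df = 1; zero margins
  are an error.
* **Spearman ρ** — Pearson correlation of mid-ranks.
* **HDI** — the shortest contiguous window over the sorted sample
  containing ⌈mass·n⌉ points; width ties resolve to the smallest lower
  bound.  Defined on the empirical sample with no smoothing so it is
  deterministic and verifiable by exhaustive window scan.

Exact/approximate switchover points (25 and 20) are fixed module
constants for cross-platform reproducibility.  The empirical size of
the continuous-data tests at α = 0.05 is verified by simulation to lie
in [0.04, 0.06]; Fisher's exact test on discrete 2×2 tables is
conservative by construction and is checked never to exceed the
nominal level.

## Expression

Genes are dropped only when their count sum is zero in *both* species
(the OR reading — drop when unexpressed in at least one species — is
available as a configuration choice).  Library sizes are column sums
of the filtered matrix.

TMM normalization follows the trimmed-mean-of-M-values recipe: the
reference sample is the one whose 75th-percentile count fraction is
closest to the across-sample mean; M and A values are computed over
genes nonzero in both sample and reference after library-size scaling;
30% of M (15% per tail) and 5% of A (2.5% per tail) are trimmed; the
factor is 2^(weighted mean M) with inverse-variance weights, and
factors are rescaled to geometric mean 1.  The precision weights use
the binomial asymptotic variance written in count *proportions*
((1−p)/p terms) rather than raw library-scaled counts; this keeps the
weight profile of the classical formula while making the factors — and
hence the normalized matrix — exactly invariant to rescaling any
sample's counts.  Normalized expression is
log2(count / (library·factor) × 10⁶ + 1).

Differential expression is a two-sided rank-sum test per gene on
normalized values (exact at 8 vs 8), BH-adjusted; the default DEG
threshold is FDR < 0.05, overridable (the stricter 0.01 used in some
settings is a config switch).  This rank-based test replaces a
negative-binomial Wald model by design: it is distribution-free,
exactly computable at this sample size, and self-contained.  The
intra- vs interspecific correlation comparison uses the rank-sum test
because the two coefficient sets are unpaired and of unequal size.

## Variance partitioning

Per gene, y = μ + u_species + v_sex + ε with independent zero-mean
random effects for the two 2-level factors (both modelled as random so
their contributions are comparable variance fractions, mirroring
common variance-partitioning practice).  Components are estimated by
REML with nonnegativity constraints and reported as fractions of
σ²_species + σ²_sex + σ²_residual.

For balanced orthogonal designs (the package's standard 2×2×r layout)
the restricted likelihood separates through three sufficient
statistics (the 1-df species and sex contrast sums of squares and the
residual SS), and the constrained optimum is found exactly by
evaluating the four KKT boundary patterns — this coincides with
truncated ANOVA method-of-moments when interior and matches `lme4`
REML to five decimals in cross-checks.  Unbalanced designs fall back
to bounded quasi-Newton optimization of the restricted likelihood with
analytic gradients (max 500 iterations, tolerance 1e-8).  Constant
responses return the degenerate split (0, 0, 1).  Fractions are
invariant to shifting and rescaling y.

A practical caveat, quantified in the tests: with two levels per
factor the species fraction rests on a single 1-df contrast, so
per-gene estimates at n = 8 + 8 are unbiased but noisy at low-to-mid
true fractions (mean absolute error ≈ 0.17 at a true fraction of
0.2–0.5, ≈ 0.03 at 0.9).  The ≥ 0.80 screen operates in the accurate
regime; interpreting individual low fractions is not recommended.
The screen threshold is inclusive (≥ 0.80, "at least 80%"), and
direction is the sign of the species mean difference on the normalized
scale (exact ties are excluded with a warning).

## Ontology

Over-representation is an upper-tail hypergeometric test of each
term's overlap with the foreground against the supplied background,
BH-adjusted across terms; terms overlapping the foreground by fewer
than 3 genes are not tested.  The annotation table is taken as given —
no ontology-graph propagation or term de-duplication.  Enriched terms
from the two direction-specific runs are pooled, de-duplicated keeping
each term's best FDR, and cut to the top 20.

The term-level expression test pairs each member gene's mean
normalized expression in species A with that in species B (the mean
across a species' samples is the chosen per-gene summary) and runs the
one-tailed signed-rank test in both directions, BH per direction
across terms; a term is called in the direction whose FDR clears the
threshold.  Both directions significant is impossible for one-tailed
pairs at reasonable n; the degenerate case is reported as no call with
a warning.

## Longevity signature

The observed statistic for a gene list is the paired one-tailed
signed-rank test on (mean in long-lived species, mean in short-lived
species); `less` encodes the anti-longevity expectation (lower in the
long-lived species), `greater` the pro-longevity one.  List genes
missing from the expression table are dropped with a log message.

The null repeats the identical test on B = 1,000 uniform
without-replacement subsamples of the same size from a background
(default: the variance-screened gene set, configurable to all
expressed genes), and the decision region is the 95% HDI of those
p-values: the observed p is `significant` only strictly outside the
interval.  Because all B draws share one study's realized expression
contrast, the null p-values are deliberately *not* uniform for small
backgrounds — they are over-dispersed by the study's tilt, which is
exactly the effect the HDI absorbs.  The over-dispersion scales like
√(list size / background size); with backgrounds at the expressed-
genome scale (~10⁴ genes) the null is indistinguishable from uniform.

## Synthetic data

The generator emulates the study design: two species (species A
declared long-lived) × 8 individuals, sex alternating F/M within
species (a balanced crossed design that keeps the 2-level REML
well-posed), per-sample library sizes, and per-gene latent log2
expression y = baseline + species + sex + residual.

Species and sex effects are fixed ±h offsets with
h = √(fraction/2)·total_sd.  The √(1/2) matches fixed offsets to the
random-effects scale the LMM estimates (a 2-level component σ²
implies a between-level sample variance of σ²/2), so REML fractions
recover the requested fractions without bias; at zero residual the
balanced-design ANOVA decomposition of the latent values equals the
requested fractions exactly because the factor cancels in the ratio.
Counts are Poisson around library-size-scaled latent proportions
(negative binomial via an optional gamma dispersion factor); residual
variability is primarily modelled on the latent log scale.

Codon pairs evolve from a random stop-free ancestor: single-nucleotide
changes are proposed uniformly; nonsynonymous proposals are accepted
with probability min(ω, 1) and synonymous ones with min(1/ω, 1), so
the realized nonsynonymous:synonymous rate ratio matches ω; proposals
creating stops are rejected; the accepted-substitution budget is
divergence × sites, split binomially between the two lineages.

The packaged fixture defaults are scaled-down study conditions chosen
once: 1,200 orthologs (vs ~12,500 in a genome-wide scan) with lengths
30–500 codons; background ω lognormal with median 0.103 and σ = 0.85
(median and ω > 1 frequency shaped like a genome-wide purifying
distribution); divergences 0.05–0.30; 5 planted ω = 3 genes with long
CDSs (600–900 codons) so the planted positive signal is decisive; 15%
of genes unexpressed in both species; 100 planted genes at species
fraction 0.95 split evenly between directions; a 30-gene planted term
inside the up-in-A half; a 19-gene anti-longevity list planted in the
up-in-B half (lower in the long-lived species); a 28-gene pro-longevity
list with no species effect; 40 random background terms of 10–60
genes.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: codon-usage bias and
site-rate heterogeneity; alignment error; >2 taxa; batch effects,
GC/length biases and realistic overdispersion structure in counts;
correlated gene modules (genes are independent given the design);
ontology term overlap/hierarchy.  Results on real data additionally
depend on upstream read processing and quantification, which are out
of scope (the pipeline starts from a count matrix).

## Reproducibility

A single global seed is expanded into independent per-stage streams by
hashing the stage name into the seed sequence, so adding a stage never
perturbs another stage's draws; every output records the seed, tables
are written with ids sorted, reals are rounded to 6 decimals in JSON
reports, and a rerun with the same config and seed is byte-identical.
The test-suite and acceptance problem sizes (e.g. 1,200-gene fixtures,
500-gene recovery strata, 1,000-term null, B = 1,000 subsamples) are
the package's chosen desk-scale study conditions.
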