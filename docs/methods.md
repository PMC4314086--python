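# Methods

## The question and the statistic

The package tests whether gene expression (and downstream phenotypic
variation) is systematically *noisier* in one sex than the other, where
noise means genotype- and environment-independent variation among
biological replicates. The per-unit noise measure is the coefficient of
variation CV = s / x̄, computed with the n−1 (unbiased-variance) sample
standard deviation. The denominator choice matters at the replication
levels this design uses (3–9 replicates); n−1 is the conventional
default and is fixed throughout.

For every analysis unit i (a transcript within one strain or pooled
genotype, or a strain/trait cell) the paired difference is
d_i = CV_F,i − CV_M,i. The test statistic is the Wilcoxon sum of signed
ranks

    W = Σ_i sign(d_i) · rank_i,   rank_i by ascending |d_i|,

with midranks for tied |d| and sign 0 for exact zero differences
(nothing is dropped; zeros keep their rank and contribute 0). W is
sensitive both to how many units are biased and to how strongly, so no
arbitrary effect-size threshold is needed. Negative W means male CVs
tend to exceed female CVs.

## The Monte Carlo null

Significance comes from a permutation null rather than the asymptotic
signed-rank distribution: all 2n CV values of the table (both sexes,
all units) are pooled, a uniform random permutation refills the n
(CV_F, CV_M) slots, and W is recomputed — 10,000 replicates by default.
`p_upper` and `p_lower` are the fractions of simulated W ≥ and ≤ the
observed W; ties count on both sides, so the two can sum to more than
one. P-values are kept as plain fractions everywhere; only the text
renderer prints a zero count as "<1/n_sim". Null percentiles use linear
interpolation (Monte Carlo noise dominates any percentile-method
difference).

Conditionally on the realized rank multiset, pooled rearrangement makes
the n signs i.i.d. uniform ±1 (a within-pair swap is equiprobable and
flips only the sign), so for tie-free data the null is the
sign-randomization law with

    E[W] = 0,   Var(W) = n(n+1)(2n+1)/6.

The test suite checks this equivalence three ways: the empirical null
variance against the closed form (within 5% at n = 500, 10,000
replicates), the null 5th percentile against −1.645·σ_W at the two
published problem sizes (n = 16,637 and 4,907), and, at n ≤ 4, the full
Monte Carlo law against brute-force enumeration of all (2n)! pooled
permutations. Whether the pool is permuted across sexes jointly or
within each sex separately is indistinguishable in law for W; the
implementation permutes the joint pool, the literal reading of
"rearranging all CV values".

## Replication structures

*Expression.* One CV per sex per transcript over a strain's biological
replicates. Strains sharing a genotype can be pooled
(`pool_by_genotype`), turning e.g. two strains × 3 replicates into one
group with 6; values are untouched, only labels and replicate indices
change. Transcripts with a non-positive replicate mean in either sex
are excluded and counted (normalized array values can dip below zero);
the analysis otherwise uses the deposited linear-scale values with no
log transform.

*Traits.* Three assay designs map onto paired CVs:
`per_individual_by_day` (unit = strain × assay day, replicates =
individuals assayed together), `vial_means` and `group_means` (unit =
strain, replicates = per-vial / per-group averages). Units lacking
either sex or with fewer than two replicates in a sex are dropped, not
errored, with a logged count — real assay tables are ragged and the
number of surviving pairs is itself a result.

## Mean–CV association

Per sex, ordinary least squares of per-transcript CV on
(1, mean, mean²) on the raw scale (a log-scale option exists), with the
plain (unadjusted) R². The female/male R² ratio asks whether the usual
mean–noise coupling explains less of the male noise; a ratio above one
indicates extra mean-independent noise in males. When the male R² is
exactly zero the ratio is reported as undefined (None), not a number.
Constant-CV input yields R² = 0 with a warning; collinear designs
raise.

## Chromatin stratification

Five-state chromatin segmentations label tracts YELLOW (broadly
expressed), BLACK/RED (repressive, nuclear-periphery associated),
BLUE/GREEN (heterochromatin). A gene gets a color only when its whole
span is contained in a *single* tract of that color (boundary equality
inclusive); a gene crossing any tract boundary — even between two
same-colored tracts — stays unassigned. This strict reading is the
default; `merge_adjacent=True` merges touching same-color tracts first.
Coordinates are 0-based half-open internally; BED is read natively and
GFF3 gene features are converted on read. Within each color, ranks are
recomputed from that color's pairs only — the published per-color |W|
values are impossible under global ranking (they exceed the per-color
n(n+1)/2 bound's scale) — while each null replicate draws *one* global
rearrangement of all colored CV values and recomputes every color's W
from it, so per-color nulls share permutations. Unassigned pairs never
enter any stratum or the pooled null.

## Dispersal analysis

Each species carries a chromosome-system tag (XY, XO, ZW, ZO) that
determines its heterogametic sex (XY/XO → male, ZW/ZO → female) and
whether that sex bears a sex-specific W/Y chromosome (XY, ZW only).
The observed statistic is the fraction of species whose heterogametic
sex disperses most, overall and within the with-W/Y and without-W/Y
subsets. The null permutes the chromosome-system tags across the *full*
table (dispersing sexes fixed) and re-derives heterogamety and subset
membership from the permuted tags — so a subset's composition is
tag-derived under the null, which is what makes the small without-W/Y
subset's null percentiles (k/5 steps) come out right. Species with
unknown or unbiased dispersal are excluded at load with a logged count.

The packaged 36-species table is a synthetic reconstruction of a
published comparative dataset whose original species list is not
redistributed here: it reproduces the published marginals exactly — 11
birds, 11 insects, 14 mammals; five species lacking W/Y; biased
fractions 29/36, 28/31, 1/5 — and its tag multiset (19 male-heterogametic
tags, 20 male-dispersing species) reproduces the published null
percentiles for the "all" subset. Species names are plausible exemplars
of each taxon/system, not the original records.

## Synthetic data: what it emulates, what it does not

`gen_expression` draws per-transcript mean abundances log-normally
(location 3.0, scale 1.0, arbitrary units), a per-transcript baseline
CV from Gamma(shape 4, scale 0.05) (mean 0.2 — typical replicate-level
array noise), and couples CV to mean as cv ∝ mean^(−0.5), a
Poisson-like mean–noise coupling shared by both sexes so that the
mean–CV regression has genuine structure under the null. Replicates are
mean × (1 + ε), ε ~ Normal(0, cv²) redrawn while non-positive; males
get cv multiplied by γ (`noise_inflation_gamma`). γ defaults to 1 — no
dimorphism — because no empirical effect size exists for it; analyses
of dimorphic data set γ explicitly, and parameter-recovery tests use
modest-noise configurations (cv ≲ 0.2) where the positivity truncation
does not bias the realized CV. The default strain layout mirrors a
six-strain design with one unique genotype and two shared ones (2 and 3
strains), giving pooled groups of 6 and 9 replicates per sex. Default
sizes mirror the deposited design: 16,637 transcripts, 6 strains, 3
replicates per strain and sex; the trait generator defaults to 200
lines, the scale of the reference-panel assays.

The generator makes no attempt to emulate probe-level artifacts,
normalization residue, transcript-transcript correlation, or technical
replication; passing tests show the inference machinery is calibrated
and directional on data satisfying its assumptions, not that real
arrays satisfy them.

`gen_traits` injects the target sex CVs at the replicate level of each
design (individuals, or group means with a small 0.05 within-group
residual). `gen_dispersal` assigns tags from a fixed composition and
makes the heterogametic sex the disperser with probability
`p_het_biased`.

## Numerical and design notes

- All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global state. Identical config + seed
  gives bit-identical output.
- The permutation engine is vectorized in chunks of 250 replicates
  (peak memory ~chunk × 2n doubles); per-replicate ranking is
  `scipy.stats.rankdata` over the chunk axis.
- Acceptance-scale runs use 10,000 replicates at n = 16,637 (~1 min on
  one core); simulation-heavy calibration tests use 400-replicate nulls
  at n = 1000–2000 over 100–200 seeds, where the 1/400 p-value
  granularity comfortably resolves the 0.05 threshold.
- `wilcoxon_w` equals 2·W⁺ − n(n+1)/2 on tie-free data, with W⁺ the
  classical one-sided signed-rank sum; asserted against
  `scipy.stats.wilcoxon` on 1,000 random instances.

## Known limitations

- The CV truncation at zero biases realized CVs downward once nominal
  CV exceeds ~0.4; the generator is not suitable for simulating
  extremely noisy transcripts without accounting for this.
- Exact replication counts of the published trait tables (405/203/174
  pairs) are not reproducible — the original record-exclusion rules are
  unspecified; the module reproduces the pairing *structure* only.
- The observed expression-side W values of the published tables require
  the original microarray dataset and are out of scope; only the
  data-independent null geometry is checked at those problem sizes.
- No phylogenetic correction in the dispersal analysis; species are
  treated as exchangeable, as in the tag-permutation design.
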