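# Methods

This note records the statistical model behind each stage of
`nutrimir`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical
conventions that a user re-implementing or auditing the pipeline needs
to know.

## Study design assumed by the pipeline

A cross-sectional cohort of healthy adults in three diet groups
(omnivore, vegetarian, vegan) of equal size, each subject contributing
one plasma small RNA-seq profile (a vector of mature-miRNA read
counts), a food-frequency questionnaire (FFQ), and age, sex and BMI.
The scientific question is whether the estimated habitual intake of
individual natural compounds (NCs) — 23 nutrients spanning
lipid-related compounds, micro-elements and vitamins, exposed as
`nutrimir.NATURAL_COMPOUNDS` — is associated with the circulating
level of individual miRNAs, in a way that is consistent across the
diet groups and not explained by age, sex or BMI.

## Intake estimation

Raw daily intake of nutrient *k* for subject *s* is the sum over food
items of `frequency (1/day) × portion (g) × amount_k per 100 g / 100`;
daily energy (kcal/day) is computed identically from the energy column
of the composition table.  Frequencies are stored canonically as
consumptions per day; readers of weekly/monthly encodings must convert
before entry, which avoids silent unit mixing.  Missing composition
values are treated as zero with a logged count (standard food-table
practice); strict mode raises instead.

Energy adjustment defaults to the **density method**: nutrient units
per 1,000 kcal (`raw / energy × 1000`).  The **residual method**
(per-nutrient least-squares residual of raw intake on energy,
recentred at the mean intake) is available via
`kcal_normalize(..., method="residual")`.  Density is the default
because it is the simplest defensible reading of "kcal-normalized"
and is scale-invariant: doubling every reported frequency leaves it
unchanged.  Subjects with zero energy intake cannot be normalized and
are excluded from the normalized table with an explicit flag.

## Count normalization and filters

Size factors follow the median-of-ratios construction: the reference
set is every miRNA with strictly positive counts in all samples (the
geometric mean is undefined through zeros); a sample's size factor is
the median over the reference set of `count / geometric mean`.  Two
conventions deserve note:

- the median is taken on the **linear ratio scale**, with even-sized
  reference sets resolved by the midpoint of the two central order
  statistics.  (Taking the median of *log* ratios, as some
  implementations do, differs only in that even-size midpoint — a
  geometric rather than arithmetic mean of the two central ratios.)
- if no miRNA is everywhere positive, the default errors and points to
  `reference="poscounts"`, which uses geometric means over positive
  entries only.

Size factors are computed jointly on all samples (not per diet group);
a per-group run can simply subset the matrix first.

Detectability is per sample: normalized reads **strictly greater**
than 15.  The *analysis set* for the correlation screen is the
group-median rule: median normalized count above 15 in at least one
diet group.  Both filters are exposed because "detectable" and
"analyzable" are distinct populations; the screen uses the
group-median rule.  The 15-read threshold is configurable
(`threshold=`), and the analysis set is monotone in it by
construction.

## Correlation screen

Within each diet group separately, Spearman's ρ between kcal-normalized
intake and normalized expression: Pearson correlation of mid-ranked
values, p-value from the t approximation
`t = ρ √((n−2)/(1−ρ²))` on n−2 df, two-sided, at all n (no exact
permutation null; this matches the behaviour of the widely used
`rcorr`-style implementations).  Pairs where either vector is constant
in any group are excluded and counted, so
`tested = |analysis set| × |NCs|` always reconciles with
`len(records) + n_dropped_constant`.

The compound filter has three parts, all configurable via
`ScreenConfig`:

| parameter | default | meaning |
|---|---|---|
| `rho_threshold` | 0.3 | applied to the absolute **average** ρ across groups (`rho_scope="per_group"` applies it to every group instead) |
| `p_threshold` | 0.05 | per-group significance |
| `min_sig_groups` | 2 | groups required below `p_threshold` |

Coherence means one strict sign in all groups; a zero coefficient in
any group breaks coherence.  `min_sig_groups=2` is the default because
requiring significance in a single group is far too permissive with
three groups of ~40; the single-group variant remains available.
No multiple-testing correction is applied at this stage by design —
the screen is a filter, not an inference; downstream confirmation and
the documented null false-positive rate (< 0.5% of pairs under the
null, measured by the acceptance suite) characterize its behaviour.

Trend classification orders the groups omnivore → vegetarian → vegan
and labels a pair *increasing*/*decreasing* only when |ρ| changes
strictly monotonically; any tie yields *none*.

Cohort comparability checks: chi-square for sex × group and BMI-class
× group, Kruskal–Wallis for age, pairwise two-sided Wilcoxon rank-sum
(Mann–Whitney) for BMI.

## GLM confirmation

For each surviving pair, ordinary least squares of transformed
expression on age (years), sex (indicator for M), BMI (kg/m²) and the
NC intake, pooled across all subjects — the covariate list contains no
diet term because diet-group structure is already enforced by the
coherence requirement; a diet-adjusted variant can be obtained by
passing diet indicators in the covariate frame.  The default response
is `log2(normalized count + 1)` (variance-stabilizing for counts; a
raw-scale option exists).  Model significance is the F-test of the
full model against the intercept-only null.

**Dominance**: the NC term is dominant when the model is significant,
`p_NC < 0.05`, and `p_NC` is *strictly* smaller than each of the age,
sex and BMI p-values (exact ties are not dominant).  Model
significance is included in the definition so that dominance always
implies a significant model; without it the two conditions can
disagree on edge cases.

## Differential expression

Subjects are split at the median kcal-normalized intake of one NC;
ties at the median go to **low** (deterministic and documented).  For
each miRNA, two nested NB2 regressions on raw counts with log link and
`log(size factor)` offset: full = intercept + age + sex + BMI + diet
indicators (reference = first group) + intake-group indicator; reduced
drops the intake term.  Dispersion α (variance `μ + αμ²`) is profiled
by maximum likelihood under the full model (bounded scalar
minimization of the negative log-likelihood over log α ∈ [−10, 4])
and shared by both fits; the statistic `2(ℓ_full − ℓ_reduced)` is
referred to χ²(1).  `log2FC = β_intake / ln 2`.

The label "LRT" here means *likelihood-ratio test* throughout.  This
is a deliberately minimal NB-LRT: one MLE dispersion per miRNA, no
shrinkage across miRNAs, no outlier replacement, no independent
filtering.  Its test surface is calibration (null rejection rate
0.03–0.07 at the 0.05 level, uniform null p-values) and parameter
recovery (mean recovered log2FC within 0.15 of a planted 2-fold
shift), not numerical parity with any published DE tool.
Non-convergent fits mark the miRNA untested with the reason recorded.

A miRNA is *expressed* for this analysis when its median normalized
count exceeds 15 in at least one intake group, and *significant* when
additionally its raw LRT p < 0.05; BH-adjusted p-values (step-up,
monotonicity enforced) across tested miRNAs are reported alongside.

## Target enrichment

Each DE miRNA contributes weight `w = −sign(log2FC) × (−log10 p_adj)`
to every annotated target gene (the sign flip encodes repression:
an up-regulated miRNA pushes its targets down); a gene's score is the
sum over targeting miRNAs.  Adjusted p-values are used as the weight
input; zero p-values are capped at the machine minimum.  This scoring
rule is this package's own definition, chosen so the enrichment stage
is self-contained and exactly testable by brute-force aggregation.

Each gene set (any GMT library) is tested by logistic regression of
the membership indicator on the gene score over the full scored-gene
universe; slope and Wald p are reported, BH-adjusted across sets.
Retention requires adjusted p < 0.05, |slope| > 0.5 and ≥ 2 scored
member genes.  With a single continuous predictor, perfect separation
is exactly a non-overlap of member and non-member score ranges; such
sets get a ridge-penalized slope (λ = 10⁻³), an undefined p, a
`separable` flag, and are never retained.  The analysis runs
separately on positively and negatively regulated miRNA subsets, since
their target-level signals point in opposite directions and would
cancel if pooled.

## Network and report

Significant pairs form a bipartite graph: miRNA nodes and NC nodes
(the latter carrying their compound class), edge attributes
`average_rho` (signed, for colour), `abs_rho`/`width`, `trend`, and
`glm_confirmed` with style solid (confirmed) vs dashed (unconfirmed).
GraphML plus node/edge TSVs round-trip all attributes exactly.  The
run report assembles the filter funnel (tested ≥ coherent ≥
significant ≥ model-significant ≥ dominant), trend and sign
percentages (one-decimal rounding), per-NC DE counts, the
configuration echo and the seed.

## The synthetic cohort generator

`generate_cohort` emulates: NB2 counts (default dispersion α = 0.2,
typical of plasma small RNA-seq; variance μ + αμ²) with per-sample
depths uniform on 0.8–1.6 million miRNA-mapped reads and log-normal
relative abundances; three equal diet groups (default 40/group → 120
subjects); sex ~ Bernoulli(0.6 female), age ~ Normal(45, 12) truncated
to [18, 80], BMI ~ Normal truncated to [16, 45] with omnivores
centred 2 kg/m² higher (so the BMI comparability check has realistic
signal); daily energy ~ Normal(2200, 350) kcal truncated to
[1200, 4000]; log-normal NC intakes with mild per-(group, NC)
multipliers emulating diet-dependent consumption.

Planted associations use a Gaussian copula: the *kcal-normalized*
intake (the quantity the screen actually analyzes) is a strictly
increasing transform of a latent normal `z₁`, and the miRNA's log-mean
receives `δ·z₂` (δ = 1.2) with `corr(z₁, z₂) = r`.  Because count
noise attenuates rank correlation, `r` is calibrated by bisection
(12 iterations against a 4,000-draw Monte-Carlo reference at the
cohort's median expression level, seeded from the spec seed) so the
*realized* Spearman ρ between intake and counts hits the target;
unreachable targets are clamped at r = 0.999 with a logged warning.
Planted miRNAs are floored at the 75th abundance percentile so they
clear the analysis-set filter.  `generate_ffq` produces a consistent
synthetic questionnaire (default 188 items, sparse consumption,
log-normal portions) and composition table for testing the intake
stage; abdominal circumference is not generated because nothing
downstream consumes it.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: miRNA–miRNA co-expression structure
(counts are conditionally independent given depth and covariates),
compositional coupling between nutrients within a diet, FFQ reporting
error and energy under-reporting, batch or extraction effects, zero
inflation beyond NB sampling, and real miRNA identities.  Recovery and
calibration results transfer to real cohorts only to the extent these
simplifications are benign.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded by the
cohort spec (calibration uses derived child seeds), so a fixed spec
reproduces byte-identical output files across runs.  The test suite
and `scripts/acceptance.py` size their simulations to run on a single
CPU in a few minutes: null calibration uses a 200-miRNA × 10-NC cohort
(2,000 pairs), 1,000 GLM and up to 1,000 NB-LRT null replicates;
recovery uses 50 replicate cohorts at 40 subjects/group and 200 (tests)
or 100 (script) DE replicates.  These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands.

## Known limitations

- The screen's t-approximate Spearman p is slightly anticonservative
  below n ≈ 10; groups that small also trip the n ≥ 4 guard.
- Dispersion is estimated per miRNA without moderation, so DE power at
  very low counts is below what shrinkage-based tools achieve.
- The logistic enrichment model treats gene scores as exchangeable
  across genes; correlated targets of the same miRNA violate this and
  the resulting p-values should be read as rankings more than strict
  error rates.
- `confirm` fits one model per pair without cross-pair multiplicity
  control, mirroring its role as a confirmation of an already filtered
  set rather than a discovery procedure.
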