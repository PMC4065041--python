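# Methods

## The analysis in brief

`revphewas` implements a reverse-genetics phenome scan for low-frequency
coding variants in an EMR-linked cohort. The premise: if a variant
disrupts gene function under a recessive (or additive) mode, its
minor-allele homozygotes should share a pattern of clinical diagnoses.
The pipeline has five stages:

1. **Screen.** For each eligible variant (MAF below a ceiling in both
   major ancestry groups, at least a floor number of minor-allele
   homozygotes), collect every diagnosis group carried by ≥2 of its
   minor-allele homozygotes, optionally drop groups recurring across
   more than 5% of all such lists, and test each remaining group with a
   two-sided Fisher exact test of affected minor- versus common-allele
   homozygotes. Heterozygotes are never counted: comparing only the two
   homozygote classes avoids committing to an inheritance model.
2. **Permutation null.** Permute each variant's genotype vector across
   subjects (independently per variant, diagnoses untouched) and rerun
   the screen; repeat ~100 times. This preserves every marginal —
   genotype counts, prevalences, comorbidity structure — while breaking
   genotype–phenotype links, and measures how many "interesting" variants
   the screen yields by chance alone.
3. **Knowledge filter.** Keep only variants whose gene carries OMIM or
   knock-out-mouse phenotype annotation, and whose screened diagnoses
   overlap the diagnosis groups mapped to that annotation.
4. **Matched exact association.** Re-test each candidate against
   common-allele homozygote controls individually matched on age
   stratum, sex, ancestry and sub-cohort, using exact conditional 2×2
   inference.
5. **Replication.** Re-test surviving pairs in an independent cohort
   under an additive dosage model with age, sex and principal-component
   adjustment, separately per ancestry, skipping phenotypes with fewer
   than 50 cases.

## Exact conditional 2×2 inference

Conditional on both margins of the 2×2 table (a/n₁ affected minor
homozygotes vs b/n₀ affected common homozygotes), the affected-minor
count A follows Fisher's noncentral hypergeometric law with odds-ratio
parameter ψ. All inference derives from this likelihood:

- **p-value** — two-sided probability method at ψ=1: the sum of all
  table probabilities not exceeding the observed one (relative tie
  tolerance 1e-7). This is the same convention as R's `fisher.test` and
  scipy.
- **Point estimate** — the conditional MLE, found by solving the score
  equation E_ψ[A] = a (monotone in ψ) with Brent's method on log ψ
  (xtol 1e-12, bracket |log ψ| ≤ 80). When a sits at the edge of the
  conditional support the CMLE degenerates to 0 or ∞ and the
  median-unbiased estimate is substituted (ψ solving the one-sided tail
  probability = 1/2).
- **Confidence interval** — exact tail inversion at α/2 per side
  (mid-p available as an option, giving narrower intervals). Bounds are
  0 or ∞ when a is at the support edge.
- **Not-estimable convention** — when no minor-allele homozygote is
  affected (a=0) the odds ratio is reported as undefined with its
  p-value intact, matching the "n/a" convention of published
  matched-control tables; fully degenerate margins (nobody or everybody
  affected) leave everything undefined.

With a single binary exposure this conditional inference is
mathematically identical to univariate exact logistic regression;
matching covariates are balanced by design rather than modelled. On the
bundled benchmark tables the CMLE reproduces published ORs closely
(e.g. 4.16 vs a printed 4.2); rows where published values differ from
both the CMLE and the cross-product reflect estimator choices of the
original analysis that are not documented and not reproduced here. In
particular, for the zero-control-cell benchmark row (1/11 vs 0/1279)
our MUE is ≈116, finite as required, but far from the printed 9.7 —
plausibly a product of the original exact-logistic software's handling
of its matching structure.

Batch Fisher p-values are computed with a flattened-support
`gammaln`-based kernel (segments reduced with `np.add.reduceat`), which
makes the permutation studies cheap; the scalar path is the same kernel.

## Matched-control design

Age strata are half-open — [0,5), [5,20), [20,45), [45,60), [60,∞) — so
a 60-year-old falls in the top stratum (resolving the printed overlap
of "45–60" with "60+"). Controls are allocated to case strata
(age stratum × sex × ancestry × sub-cohort) proportionally by largest
remainder and sampled without replacement. When a stratum's pool is
empty the matching relaxes in a fixed, logged order: drop the
sub-cohort factor, then widen to adjacent age strata; sex and ancestry
are never relaxed. The control count comes from a two-proportion power
calculation (detect 30% vs 10% with 25 cases, α=0.05, power 0.80),
clamped to the 800–1,800 range. Three power methods are reported side
by side because they genuinely disagree at this design: the pooled
normal approximation needs ≈800 controls; the arcsine approximation
never reaches 80% power at 25 cases; the simulated exact Fisher test
plateaus near 0.805 and crosses 0.80 only around 4,000–5,000 controls
(the conservatism of the exact test at 25 cases). The normal
approximation is used operationally.

## Multiplicity in the permutation comparison

Counting "variants with a Bonferroni-significant diagnosis" requires a
denominator. The default corrects per variant over that variant's own
post-filter tested-diagnosis count (a `global` option divides by the
total number of tests instead). Quartiles of the null distribution use
linear interpolation; the real value's percentile is its mid-rank among
replicates. The permutation replicates screen the *same* variant panel
as the real data — eligibility is computed once, on real genotypes —
because permuting across ancestries drifts per-ancestry MAFs toward the
pooled mean and would otherwise silently change the panel.

## Knowledge-base concordance

Expert review is emulated, not reproduced: each gene's annotation terms
carry a set of mapped diagnosis groups, and a variant passes when at
least one screened diagnosis falls in its gene's mapped groups (the
match fraction threshold defaults to 0; raising it demands more
overlap). Direction of effect is deliberately ignored — a pattern
opposite to the annotated loss-of-function phenotype still counts, as a
gain-of-function allowance. A post-hoc record-review step is emulated
by a configurable per-(variant, phenotype) exclusion list; the pipeline
reports candidates before and after exclusions.

## Replication model

Cases have ≥1 code in the phenotype's groups, controls none. The model
is logistic in the minor-allele dosage (0/1/2) with age, sex and the
first 3 PCs; fitting is Newton IRLS (score tolerance 1e-8, ≤100
iterations) via statsmodels. Wald p-values and CIs are the default
(LRT available). Complete or quasi-complete separation (non-convergence,
infinite SE, or |log OR| > 15) is flagged rather than reported as a
finite effect. EA and AA are analyzed separately and never pooled;
cohorts are restricted to ages above 30 by default; phenotypes with
fewer than 50 cases in an ancestry stratum are skipped ("<50" is the
operative reading of the case floor).

## The synthetic cohort generator

Because the motivating data cannot be shared, all studies run on
generated cohorts designed to reproduce the structure the analysis
relies on:

- **Genotypes** are Hardy–Weinberg draws, dosage ~ Binomial(2, q), with
  per-ancestry allele frequencies drawn uniformly in [0.01, 0.10]
  ("other" ancestry uses the EA/AA mean). Missing calls are
  missing-completely-at-random at 5% by default; real platform-merged
  missingness is structured, not MCAR, and is not emulated.
- **Demographics** default to the discovery-cohort scale: 8,546
  subjects, sub-cohorts in proportions 3,174/1,558/3,940, ancestries
  69.4% EA / 20.1% AA / 10.5% other, 47% male. Ages mix 90%
  N(mean+5, 0.78·sd) with 5% U(0,5) and 5% U(5,20), giving mean ≈52,
  SD ≈18 while populating all five matching strata.
- **Diagnoses** use per-group prevalences log-uniform in
  [0.005, 0.20] and a block comorbidity model: groups sit in blocks of
  5; each subject activates a block with probability 0.2, multiplying
  within-block risk 3× (marginals preserved). This reproduces the
  false-positive clustering of correlated EMR codes without a full
  copula. Block parameters are free: no quantitative comorbidity
  structure was available to match.
- **Planted effects** multiply a group's odds by ORˣ where x is the
  recessive indicator or the additive dosage, applied to the
  pre-missingness genotype; marginal prevalence of the planted group
  can be pinned (the studies pin it at 0.10).
- **Knowledge base** pairs each planted gene with a term mapping to its
  true group; decoy genes receive random-group terms at a configurable
  rate (0.5 in the studies).
- **Replication cohorts** add ancestry-shifted unit-variance Gaussian
  PCs (EA/AA means ±1 on PC1, halved per axis).

What the generator does *not* emulate — raw ICD-9 vocabularies and
their rarely-used-code artifacts, longitudinal encounters, LD between
variants, structured missingness — bounds what passing tests show: they
validate the statistical machinery and the funnel's operating
characteristics, not performance on real EMR text or real genotyping
platforms.

### The cross-list filter at synthetic scale

The >5%-of-lists exclusion exists to remove rarely-used raw codes that
recur across many variants' shared lists in a many-thousand-code
vocabulary. Applied to a 100-group ontology of moderately prevalent
groups it inverts its purpose: any group with prevalence ≳1% appears on
most shared lists *by construction* (≥2 carriers among ~15 homozygotes
is likely) and would be excluded — including planted effects. The
filter is therefore implemented exactly (strict inequality, denominator
= variants with non-empty lists, threshold configurable) but switched
off (`list_freq_max=1.0`) in the synthetic-cohort studies.

## Study designs and problem sizes

The canned studies in `revphewas.studies` fix the validation
conditions: null calibration and planted separation use 2,000 subjects
× 200 variants × 100 groups with 100 permutation replicates (planted:
one recessive OR-20 effect at MAF 0.09, prevalence 0.10, no missing
calls); funnel recovery uses 8,500 subjects × 120 variants × 80 groups
with one recessive OR-5 effect at MAF 0.08, prevalence 0.10, and a
noise-0.5 knowledge base; replication calibration uses 5,000 subjects
with a planted per-allele log-OR of 0.5, and 100 independent null
phenotypes for the type-I rate.

A structural note on the planted-separation study: a single planted
variant adds exactly +1 to an otherwise exchangeable
Bonferroni-significant count, so the real count can exceed the maximum
of 100 null replicates only when the null count distribution is nearly
degenerate. At this scale it is not (null counts range over roughly
1–14), so the exceedance probability is near zero regardless of effect
size — the informative planted readout is whether the planted variant
itself is Bonferroni-significant, which is also reported.

## Numerical and degenerate-input conventions

- Fisher tie tolerance 1e-7 (relative) on table probabilities; p-values
  clipped into (0, 1].
- CMLE/MUE/CI root-finding on log ψ with Brent xtol 1e-12 in |log ψ| ≤ 80;
  unreachable targets return the nearer bracket endpoint.
- Variants with every call missing are excluded from eligibility with a
  warning; unknown diagnosis codes are dropped with a warning (dirty
  EMR dumps should not abort a run); unknown groups in a phenotype
  definition are an error (definitions are analyst-authored).
- The homozygote eligibility floor is inclusive (≥10 by default) and
  configurable, reconciling the two published phrasings ("more than 10"
  vs "less than 10 excluded") in favour of the weaker reading.
- Minor-allele polarization of dosages is cohort-wide; per-ancestry
  MAFs are still used for eligibility.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical configurations give byte-identical
  outputs.

## Known limitations

- Set-overlap concordance cannot reproduce subjective expert review;
  candidate counts are sensitive to how knowledge-base terms are mapped
  to groups.
- Exact conditional inference is implemented for the 2×2 case only; no
  multi-covariate exact logistic regression, and no conditional
  regression on matched pairs.
- The matching allocator takes what a stratum has when the pool runs
  dry after all relaxations (logged), so extreme designs can return
  fewer controls than requested.
- The generator draws variants independently (no LD) and diagnoses with
  only block-level correlation; both understate the redundancy of real
  data.
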