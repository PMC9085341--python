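# Methods

## Problem and scope

A DRG payment system needs case-mix groups whose members consume similar
resources. Within one adjacent DRG (ADRG) — here a cerebral-ischemia
inpatient group — the workflow is: clean the discharge abstracts, decide
whether the group is heterogeneous enough to subdivide (cost coefficient of
variation above 1), identify cost drivers, grow a grouping tree over the
significant categorical factors, check within-group homogeneity and
between-group separation, and publish per-group payment standards. The
package implements this single-ADRG workflow; it does not implement a full
national grouping scheme, ICD dictionary validation, or reimbursement
adjudication.

## Cleaning and severity

Exclusion criteria run in a fixed order — (1) missing or invalid items,
(2) principal diagnosis or principal (first listed) procedure outside the
scheme code set, (3) LOS > 60 days, (4) cost percentile trim — and each
record is logged under the first criterion it violates, which makes the
exclusion log additive and reproducible. The trim bounds are linear-
interpolation percentiles (default 1st/99th) computed on the cohort
surviving criteria 1–3; records strictly outside the bounds are dropped.
The percentile convention and bounds are configurable; `trim=None`
disables criterion 4 entirely.

Severity: a case is MCC if any secondary diagnosis is on the MCC inclusion
list and the primary diagnosis is not on that code's exclusion list,
else CC by the same rule, else Non-CC; MCC takes precedence and the result
is independent of the order of secondary diagnoses. Age bands are 0–17,
18–65, > 65 with inclusive upper bounds; age 0 is admitted into the lowest
band (the cohort's reported age range starts at 0 even though summary
tables label the band "1–17"). The long-stay indicator is LOS > 30 days.

Currency is held as floating point internally and rendered/parsed at two
decimals (round half to even) at I/O boundaries; at these magnitudes that
is cent-exact and keeps the statistics vectorised.

## Synthetic cohort generator

The generator emulates the *cleaned* study cohort — the deliverable of the
cleaning stage, not the raw feed. Covariates (sex, age band, allergy,
insurance, admission route, discharge mode, CC level, long stay, admission
year) are independent categorical draws matching the published marginal
prevalences; only marginals are published, so no correlation structure is
imposed (hooks exist via `category_probs`). Expected cost is
multiplicative,

    E[cost] = b · Π_f m_f(level_f),

with the published cost ratios as multipliers (male 1.05; age 18–65 2.22,
> 65 2.63; emergency 1.20; CC 1.48, MCC 2.25; long stay 4.23; transfer
1.76, death 1.55, other discharge 1.35; reference levels 1). Realised cost
is Gamma(mean µ_i, shape k) with constant shape, mirroring the fitted
model family. Two calibration targets, cohort mean 17,206.09 and cohort CV
1.18, fix `b` and `k` in closed form: with R the (random) multiplier
product and E[R], E[R²] available from the independent factor moments,

    b = target_mean / E[R],
    CV² + 1 = (1 + 1/k) · E[R²] / E[R]²  ⇒  k ≈ 1.563.

LOS is a moment-matched log-normal (mean 10.70, SD 8.61) sampled by
inverse CDF inside [1, 30] or [31, 60] according to the drawn long-stay
indicator, rounded to whole days. Cost components follow a
Dirichlet-jittered split of the pooled published composition shares and
close exactly on the total (residual absorbed by the largest component).
Diagnosis/procedure codes come from a synthetic universe: MCC/CC/neutral
secondary codes with a sparse primary-exclusion map, drawn consistently
with each record's severity level. Everything is deterministic in the
seed.

`generate_study_cohort` additionally produces a raw cohort of 6214 records
engineered so the four criteria retain exactly 5204 (300 missing, 301 bad
code, 301 over-long stays, 108 trimmed), exercising the cleaning
bookkeeping at the study's scale.

What the generator does **not** emulate: factor correlations (e.g. age ×
comorbidity), within-year seasonality, readmissions, real code ontologies,
year-specific cost effects, and the extreme pre-trim cost tail of real
claims. Consequently, passing recovery tests demonstrates correctness of
the estimators under the stated multiplicative-gamma conditions, not
robustness to real-data misspecification. One operational consequence: the
pipeline's synthetic source skips the percentile trim (`trim="auto"` →
none), because re-trimming a cohort generated to match an already-trimmed
one cuts its CV from ≈ 1.18 to ≈ 0.90 and falsifies the subdivision
premise; file sources keep the (1, 99) default.

## Rank screening

Two-level factors use the Mann–Whitney U test: midranks, U of the first
group, normal approximation with tie-corrected variance, two-sided p;
continuity correction off by default (configurable), matching common
statistical-package defaults. An exact permutation path
(`method="exact"`) is available for small samples. Multi-level factors use
tie-corrected Kruskal–Wallis H with a χ²(k−1) reference. Reports carry
per-level n, share and rank mean; rank means weighted by group size always
average to (N+1)/2, and both tests are invariant to monotone transforms of
cost. All-tied inputs return statistic 0 and p = 1.

## Gamma regression

`GammaCostModel` delegates the IRLS fit to statsmodels (Gamma family, log
link; default tol 1e-8, max 100 iterations), with dispersion estimated by
Pearson χ²/df and Wald intervals on the log scale exponentiated to cost
ratios. Degenerate designs raise a singularity error naming the column;
non-convergence raises an error carrying the deviance trace. Marginal
means average response-scale predictions over a *balanced* grid (equal
weight per combination of the other factors' levels): under the log link
this makes marginal-mean ratios equal the cost ratios exactly, and matches
the magnitude pattern of the published marginal means, which greatly
exceed raw group means (observed-margin weighting is available via the
grid hook). Differences to the reference marginal mean are computed from
unrounded values.

## Grouping trees

**Exhaustive CHAID.** For a continuous target, each predictor's observed
categories are merged into the partition whose one-way ANOVA p is
smallest. With c ≤ `exhaustive_limit` (default 6) categories every
admissible partition is scored directly — all set partitions for nominal
predictors, contiguous partitions for ordinal — which guarantees the
returned partition is the global optimum; for larger c the classic
sequential scheme (repeatedly merge the least-significant pair, remember
the best partition seen) is used. The trivial one-group partition
participates with p = 1, so a signal-free predictor collapses entirely;
ties prefer fewer groups, then canonical category order. The winning
predictor's best raw p is Bonferroni-adjusted by the number of ways its c
categories can form the chosen k groups — the Stirling number S(c, k) for
nominal scales, C(c−1, k−1) cut-point choices for ordinal — and a node
splits (multiway) only if the smallest adjusted p is ≤ `alpha_split` and
every child holds at least `min_child_n` records. Ties across predictors
break by the declared predictor order, making the tree deterministic;
permuting the input rows does not change it.

Degenerate ANOVA inputs are defined as: no between-group variation → (F=0,
p=1); between-group variation with zero within-group variance → (F=∞,
p=0). Adjusted p is capped at 1 and never smaller than the raw p.

Defaults: α = 0.05, Bonferroni on, `min_parent_n` 100, `min_child_n` 50,
depth ≤ 5 — sized so that 5–12 leaves are plausible at n ≈ 5,000. Age band
is ordinal (adjacent merges only); sex, admission route, discharge mode
and CC level are nominal, with a config toggle to treat CC level as
severity-ordered. The long-stay indicator is excluded from the default
predictor list: lengths of stay vary too much across institutions to be a
defensible payment-grouping variable, so it informs the regression but not
the tree. Merged categories are never re-split, and there are no
missing-value branches (the cohort is complete after cleaning). Trees
serialise to a documented JSON structure; leaf labels concatenate the
path's category conditions. Records whose category was unseen at a node
route to the largest child.

**CART baseline.** Binary splits over the same predictors, chosen to
maximise the within-node SSE reduction over all 2^(c−1)−1 binary category
partitions (c−1 cut points if ordinal), same stopping sizes, optional
weakest-link cost-complexity pruning (`ccp_alpha`). Model comparison
reports the Pearson correlation between leaf-mean predictions and observed
costs, the mean absolute error, the standard deviation of the errors
(interpreted as SD of signed prediction errors), and the leaf count; a
single-leaf model is flagged degenerate with correlation reported as 0.

## Validation and payment

CV uses the sample (n−1) standard deviation over the mean. Subdivision of
a parent group is recommended strictly when CV > 1; a fitted grouping is
acceptable when each group's CV is ≤ 1, with singleton groups flagged and
their CV undefined. Between-group separation uses the Kruskal–Wallis test
from the screening module. Payment standards per group: median (standard
cost), quartiles by linear interpolation (configurable to other quantile
conventions), upper limit P75 + 1.5·IQR, and excess cases strictly above
the limit — computed on the cleaned cohort, consistent with the cleaning
order. Reported currency rounds at two decimals, half to even.

## Problem sizes and numerical choices

Simulation-based tests run at the cohort's own scale (n = 5204) for
recovery and determinism checks, n = 50,000 for prevalence convergence,
2,000 replicates for type-I-error calibration, and ≤ 12-observation inputs
for the brute-force partition oracles; these sizes give comfortable
Monte-Carlo margins for the stated tolerances. The tie-break rules
(predictor order, fewer groups first, canonical category order) exist
solely to pin down determinism; alternative conventions would yield
equally valid trees.

## Known limitations

* Independent covariates understate real-world confounding between age,
  severity and discharge mode; recovered coefficients on synthetic data
  are therefore cleaner than a real cohort would allow.
* The exhaustive-CHAID adjusted p-values inherit the usual CHAID caveat:
  the Bonferroni multiplier over-corrects for ordinal predictors with
  few categories and under-corrects after exhaustive search, so
  `alpha_split` should be read as a tuning knob, not a strict error rate.
* With every predictor at ≤ 4 categories the merge search is always truly
  exhaustive; the sequential fallback is only exercised for predictors
  with more categories than `exhaustive_limit`.
* The published benchmark upper limits are reproducible to the cent from
  their printed P75/IQR inputs for most groups, but printed rounding makes
  a one-cent discrepancy unavoidable in one row; recomputation from raw
  costs is exact by construction.
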