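# Methods

This note records the conventions, parameter choices, and design decisions
behind `ctpet`, and what the synthetic-cohort tests do and do not
establish about real data.

## ctDNA quantification

A called gene mutation is **positive** when its VAF ≥ 0.25% (boundary
inclusive); copy-number and structural variants carry no VAF and count
toward gene- and sample-level positivity by presence, but are excluded
from all VAF aggregates. Per sample and timepoint:

- relative abundance = max VAF × cfDNA (ng/ml), a unitless burden score;
- ctDNA concentration = mean VAF × cfDNA (pg/ml) / 3.3 pg per haploid
  genome equivalent, in hGE/ml.

Both aggregates range over *positive* mutations only — the 0.25% rule
defines what counts as detected. Because that choice is a convention, the
`positive_only=False` switch ranges them over all called rows instead.
When nothing passes the threshold both metrics are defined as 0, matching
"ctDNA-negative" semantics while keeping the metrics total. Missing
cfDNA or PET values propagate as missing and are never imputed as zero.
VAF is accepted as a fraction in [0, 1]; out-of-range rows are rejected,
never silently rescaled.

Clearance is a pure function of the (pre-positive, post-positive) pair:
cleared / persistent / newly-detected / consistently-negative, evaluable
at whole-sample scope or per gene.

## The published risk rule and its sign convention

The frozen model is exactly the printed two-term linear score
(−0.9858 × SUVmean − 0.0109 × ctDNA concentration, no intercept) with the
printed rule *low risk ⇔ score ≤ −2.6616*, boundary inclusive. Taken
verbatim, this rule has a counterintuitive orientation: both coefficients
are negative, so a patient with *more* residual disease (higher SUVmean or
ctDNA burden) gets a *lower* score and lands on the "low-risk" side. The
package implements the rule exactly as printed and pins that behavior in a
test; `ModelSpec.low_risk_rule` and the `low_is_lowest` flag of
`tertile_stratify` expose the direction explicitly so an analysis can use
the orientation consistent with the survival claim (low risk = least
burden = top tertile of the score), as the bundled survival driver does.
Whether the printed cutoff was derived from tertiles of the combined
cohorts or another rule is not documented; it ships as a constant.

## Statistical kernels

All kernels are implemented in `ctpet.stats`; scipy contributes only
distribution functions and `rankdata`. Conventions, each pinned by a test
against an independent oracle:

- **AUC** is the midrank (ties count ½) statistic; the DeLong variance
  uses placement values, and the 95% CI is on the AUC scale, truncated to
  [0, 1] (no logit transform) — matching the style of CIs printed near 1.
- **Paired DeLong test**: placement-value covariances; identical score
  vectors give z = 0, p = 1; a zero-variance difference with unequal AUCs
  is reported non-evaluable rather than p = 0. The implementation agrees
  with R `pROC` to 1e-9 and converges to an exact marker-swap permutation
  test as n grows. At n ≈ 12 the asymptotic p can differ from the exact
  permutation p by ~0.1 — an inherent small-sample property of the test,
  not an implementation artifact.
- **Youden cutoff**: candidates are midpoints between consecutive distinct
  scores plus sentinels, so separable classes get a strictly separating
  (midpoint) cutoff; ties in J break toward higher specificity.
- **Fisher's exact test**: two-sided p sums hypergeometric probabilities
  of tables no more probable than the observed one (the R `fisher.test`
  convention), with a 1e-7 relative guard against pmf round-off; the odds
  ratio is the sample odds ratio. Degenerate margins give p = 1.
- **Wilcoxon rank-sum**: midranks; exact enumeration of rank assignments
  when both groups have ≤ 8 observations (valid under ties), otherwise the
  normal approximation with tie correction and 0.5 continuity correction.
- **Kaplan–Meier**: product-limit with censorings at an event time counted
  at risk for that event; with no censoring it reduces exactly to the
  empirical survival fraction.
- **Log-rank**: Mantel–Haenszel observed-minus-expected over event times
  with hypergeometric variances, 1-df chi-square.

## Model building

- **LASSO selection**: columns standardized internally; penalty path of
  100 log-spaced values from the data-derived maximum (the smallest
  penalty with an all-zero solution) down 3 decades; the penalty minimizes
  10-fold stratified cross-validated deviance (no one-standard-error
  rule); selection is reported on original names. The L1 optimum is not
  unique under perfect collinearity, so exactly collinear duplicates keep
  only the first (deterministic tie-break). Zero-variance columns are
  dropped with a warning.
- **Stepwise pruning**: bidirectional on logistic AIC, scoped by default
  to the LASSO-selected set (drop any current term, re-add any previously
  dropped one); moves are evaluated in lexicographic order and the best
  strictly improving move is taken, so the procedure is deterministic.
- **Logistic integration**: unpenalized maximum likelihood; quasi-complete
  separation (all fitted probabilities within 1e-6 of their labels) is
  flagged on the returned spec instead of diverging silently.
- **LOOCV**: refits only the coefficients per fold on the fixed feature
  set and pools the **intercept-free linear score** across folds. Pooling
  per-fold probabilities is biased: fold intercepts are incomparable, and
  under a null model the intercept anticorrelates with the held-out label
  (leaving out a positive lowers it), dragging the pooled AUC well below
  0.5. The intercept-free score removes that artifact and matches the
  published score convention; nested per-fold re-selection is available to
  callers that want it.
- **Tertile stratification**: the boundary is the ⌈n/3⌉-th order statistic
  of the scores; boundary ties go to the boundary-inclusive side;
  all-equal scores collapse to one group with a degenerate flag.

A known property of the pinned selection procedure: minimum-CV-deviance
LASSO over-selects, and AIC retains an already-selected noise variable
with probability ≈ 0.15, so the selected set usually contains, but is not
always exactly, the truly informative pair. The tests assert what the
procedure delivers (planted effects always recovered; compact models).

## Modules and hub genes

PPI modules are Louvain communities of the panel-restricted interaction
graph at **resolution 0.5**, seeded and size-bounded to [3, 500] with
oversized communities re-clustered at full resolution (indivisible ones
hard-split). Plain modularity (resolution 1, CNM or Louvain) splits a
densely connected gene set whenever a member has a single outside
neighbor — the pendant pathology of modularity on panel-sized graphs —
which breaks planted-clique recovery (measured 59–64/100 versus 100/100
at resolution 0.5); the lower resolution is the standard remedy when
coarser communities are wanted. Treatment modules mirror the annotation
file exactly (one module per paradigm, multi-membership across paradigms
allowed, duplicates deduplicated with a warning).

A module's discrimination uses its post-treatment **binary any-mutation
status** by default (count mode and pre-treatment status are options),
oriented so that mutation predicts non-pCR; constant status vectors score
0.5 with a degenerate flag. Hub genes are the intersection of all modules
with AUC strictly above 0.65; when both module systems are present, at
least one qualifying module per system is required (else the plain
intersection is used, with a note). Note the semantics of that
intersection under a threshold sweep: raising the threshold removes
modules from the intersection and can therefore *enlarge* the hub set
before it empties — the tests pin this behavior.

The community-detection step stands in for an external enrichment service
used in the original workflow; module identities therefore depend on the
supplied network, and the literal published module memberships (P1–P6,
T1–T6) are not reproducible without that service's snapshot. The
convergence logic does not depend on them.

## Region analysis

Transcript models list exons as 1-based inclusive genomic intervals in
transcript order (strand-aware: exon 1 is the 5′ end, so on the minus
strand it has the highest coordinates). Exon bounds are inclusive on both
ends; intron K is the gap after exon K in transcript order; positions
outside the span are "outside"; indels are assigned by start coordinate.
Exon mutation counts deduplicate by (chrom, pos, alt). The bundled
11-exon driver transcript is a **synthetic fixture on arbitrary
coordinates — it is not the true TP53 transcript**, and exon numbering is
relative to whatever model is supplied.

## The synthetic cohort generator

The generator draws, per patient: response ~ Bernoulli(pCR rate); pre-NICT
per-gene carriage from marginal prevalences; post-NICT carriage by
response-conditional retention; lognormal VAFs (truncated to (0, 1] by
rejection) and cfDNA; lognormal PET metrics with response-conditional
post-NICT parameters (SUVmax is SUVmean times a lognormal factor; TLG is
exactly SUVmean × MTV); pathology areas consistent with the drawn response
class; exponential DFS/OS by latent risk group with administrative
censoring (plus an off-by-default uniform-dropout toggle). Survival
attaches to the risk group, not the response directly — the simplest
model that makes Kaplan–Meier/log-rank recovery testable.

Key defaults (all overridable), chosen to encode the study's printed
cohort facts:

| parameter | default | rationale |
|---|---|---|
| n_patients | 68 | discovery cohort size |
| pcr_rate | 0.25 | pCR in ~22–31% of patients |
| tp53_prev_pre | 0.63 | pre-NICT TP53 carriage 63% |
| other_gene_prev | EGFR/PIK3CA 0.07; MET, ATR, NFE2L2, ESR1, BRCA2, CDKN2A 0.04 | frequently-altered panel genes; jointly calibrate pre-NICT detection to ≈ 0.75 |
| clearance_prob_pcr | 1.0 | ctDNA cleared in all pCR patients |
| clearance_prob_nonpcr | 0.52 | calibrates post-NICT detection to ≈ 0.31 analytically: detection_post = (1 − pcr_rate)(1 − ∏(1 − (1 − clearance)·prev)) |
| vaf_lognormal_params | (ln 0.02, 1.0) | low-frequency ctDNA regime, right-skewed, median 2% |
| cfdna (pre/post), ng/ml | lognormal (ln 10, 0.5)/(ln 8, 0.5) | typical plasma cfDNA range |
| suvmean post (pCR / non-pCR) | lognormal (ln 1.3, 0.30)/(ln 3.2, 0.45) | responders' metabolic activity collapses; pre-NICT identical across groups |
| driver_exon_fraction | 0.85 | deep panels enrich coding regions; reproduces the exon-dominant driver mutation pattern |
| hazards (DFS, /month) | 0.008 low / 0.035 high | clear but realistic separation over a 36-month horizon |
| censor_horizon | 36 months | follow-up duration |
| unresected_prob_nonpcr | 0.11 | ~6/53 unresectable non-pCR patients, retained as non-pCR and excluded from DFS |

The distributional forms (lognormal VAF/cfDNA/SUV, exponential survival)
are modeling choices — the source publication states none.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: sequencing error and clonal-hematopoiesis
artifacts (assumed removed upstream); co-mutation correlation between
genes (carriage is independent per gene); CNV/SV beyond a class label;
within-patient correlation between ctDNA burden and PET metrics beyond
their shared dependence on response (real data couples them continuously,
so synthetic AUCs run higher than published ones); tumor-growth dynamics;
competing risks (deaths without recurrence are censored for DFS). The
synthetic cohorts validate the *machinery* — estimators, conventions,
determinism, planted-structure recovery — not clinical effect sizes.

## Problem sizes and numerics

Simulation-backed tests use the sizes at which the checked property is
decisive while keeping the suite fast: marginal calibration at n = 10 000
(99% binomial intervals); logistic parameter recovery at n = 20 000
(±10%); LOOCV null calibration at n = 200 over 100 seeds; end-to-end
hub-gene recovery at n = 400 over 100 seeds; selection-consistency checks
over 5–6 seeds at n = 400–500. Logistic fits converge at tolerance 1e-10;
ROC curves carry ±∞ sentinel cutoffs; all stochastic steps take explicit
seeds recorded in the run manifest, and a pipeline run is byte-identical
given the same config and seed.

## Known limitations

- The published per-cohort AUCs and survival p-values depend on
  undeposited patient-level data; this package reproduces the published
  *procedure* and the exactly recomputable worked value (the −2.6616
  cutoff), not those cohort-dependent numbers.
- The printed risk rule's orientation (see above) is preserved verbatim;
  analyses that want "low risk = better prognosis" must use the direction
  flags.
- Module identities depend on the supplied PPI network and annotation;
  only the convergence logic is intrinsic.
- The VCF reader is a convenience for minimal single-sample files with an
  AF-style INFO field; the canonical interchange is the documented TSV.
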