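# Methods

## The comparison being made

One death, two verdicts: the minimally invasive autopsy (MIA) assigns a main
cause of death (CoD) blind to clinical information; the complete diagnostic
autopsy (CDA), integrating macroscopic examination and clinical data, is
treated as the gold standard. Every analysis in this package is a function
of those paired verdicts. The main CoD is always the *direct* cause — the
condition in the chain that led to death — never an underlying condition
such as HIV or malnutrition, which are carried separately on the verdict
(`underlying`, up to four `chain` entries, `other_significant`).

## Evidence grading and certainty

Two ordinal 0–4 scales grade the strength of each arm's findings: pathology
(0 none/nonspecific … 4 severe findings likely to cause death) and
microbiology (0 no organism … 4 true pathogen and/or organism consistently
detected in ≥4 samples). A third input is the Y/N concordance between the
organisms identified and the histological lesions; it is structurally
inapplicable (must be absent) when either score is 0.

Certainty of diagnosis is a *lookup*, not a formula: the 5×9 expert matrix
is stored cell for cell (`evidence._MATRIX`) and exported flat via
`certainty_matrix_rows()` for audit. One rule precedes lookup: if an
organism was seen histologically in association with inflammatory changes,
the pathology score is incremented (capped at 4), exactly once —
`adjust_pathology` clears the flag, and `certainty()` refuses grades with
the flag still pending so the adjustment cannot be skipped or doubled.
The matrix is monotone in each argument (checked exhaustively in tests):
more evidence never lowers certainty.

A verdict is *nonconclusive* exactly when its certainty is "no diagnosis";
the data model enforces the biconditional, and nonconclusive verdicts carry
no ICD-10 code (empty `*_code` field in the CSV).

## ICD-10 hierarchy and coincidence

Codes are parsed to (letter, two digits, optional one-digit subdivision);
chapter XXII (U) codes and dagger/asterisk suffixes are rejected — they do
not occur as CoD main codes. Chapter/block resolution uses the WHO ICD-10
(2016) block ranges, shipped as a human-readable TSV
(`miaconcord/data/icd10_blocks.tsv`) and overridable per run: the edition
of the boundaries is a data choice, not code. Chapters are derived as the
envelope of their blocks; the loader rejects overlapping blocks or
chapters, so every category resolves to at most one of each. Range
comparison is plain string order on `letter+NN`, which is the ICD-10
collating order; blocks are closed ranges (B99 belongs to B99–B99).

Coincidence of two codes is the depth of their deepest shared level:
identical full code → perfect; same 3-character category → almost perfect;
same block → moderate; same chapter → low; otherwise none. Two identical
3-character codes with no fourth character are *perfect* (identity), not
almost perfect. The relation is symmetric and monotone in shared-prefix
depth (property-tested over random valid codes).

## Disease categories

The five-category classification (infectious / malignant / congenital /
other / nonconclusive) follows the clinical nature of the condition, so it
cannot be derived from the ICD chapter alone; it is a packaged, editable
YAML mapping. Keys may be chapter ids, category ranges, or single
3-character categories; resolution is most-specific-first (category >
narrowest range > chapter > fallback "other"). The default maps chapter I
to infectious; C00–C97 to malignant (benign and in-situ neoplasms D00–D48
fall through to "other"); chapter XVII to congenital; the infection-caused
blocks outside chapter I (G00–G09 CNS infections, J09–J18 pneumonia,
J20–J22 acute lower respiratory infections, K65–K67 peritonitis, N10–N16
pyelonephritis) to infectious; and R95–R99 to nonconclusive. Range keys
beyond literal WHO blocks (e.g. C00–C97) are accepted at block precedence
because the malignant range spans fifteen blocks.

## Agreement statistics

Cohen's kappa is computed from the 5×5 confusion matrix (rows MIA, columns
CDA) in the fixed category order. Two standard errors are reported, because
they answer different questions:

* `se_null` — the variance of kappa under independence (H₀: κ = 0),
  `var0 = [p_e + p_e² − Σ r_i c_i (r_i + c_i)] / (n (1 − p_e)²)`; this is
  the SE classically printed beside a kappa test statistic.
* `se_alt` — the Fleiss–Cohen–Everitt large-sample variance under the
  alternative, the correct basis for a confidence interval on κ itself.
  The 95% CI is κ ± 1.96·se_alt, truncated to [−1, 1].

Both appear in every report so the distinction stays auditable; the
implementation is cross-checked in tests against an independent
direct-summation oracle (to 1e−12 on 1,000 random matrices) and against
statsmodels' `cohens_kappa` (value and both SEs). Interpretation uses the
Landis–Koch bands with closed upper bounds (0.61–0.80 = substantial).

Per-category accuracy collapses the matrix one-vs-rest: tp is the diagonal
cell, fn the rest of the CDA column, fp the rest of the MIA row. All
proportions get exact Clopper–Pearson 95% CIs via beta quantiles; at k = 0
(or k = n) the interval is one-sided by construction, with the bound at
exactly 0 (or 1). A metric with a zero denominator is *not applicable*
(`None`, rendered "N/A") — never 0/0. The coincidence tabulation includes
only category-concordant cases, so its denominator equals the
confusion-matrix diagonal sum (asserted as an invariant); concordant
nonconclusive pairs carry no codes and are counted in the denominator but
not graded.

Display rounding is percentages to 0 dp, kappa to 2 dp, SEs to 4 dp; the
JSON report keeps full precision.

## The packaged example series

`data/example_cases_synthetic.csv` holds 54 paired cases whose category
cross-tabulation, per-category coincidence counts, and per-arm certainty
distributions reproduce a published pediatric validation series' marginal
tables (confusion diagonal 39/7/0/2/0; coincidence 32 perfect-or-almost /
4 moderate / 3 low / 9 none over 48 concordant cases, including the nine
cross-chapter pairs — pneumonia vs other bacterial diseases, vs viral CNS
infection, vs peritonitis, vs pyelonephritis). The *per-case* codes are
synthetic: the original case-level listing is not publicly deposited, so
plausible pediatric CoD codes were chosen to hit the published margins
exactly. Statistics computed from margins (kappa, agreement, accuracy,
coincidence counts) are therefore exact; nothing case-specific should be
read from individual rows. A few rows exercise the pathology-adjustment
rule (stored pre-adjustment with the histology flag set).

## Synthetic generator

`SimDesign` fixes: the CDA category distribution π; a row-stochastic
misclassification matrix C with `C[j, i] = P(MIA i | CDA j)`; depth
probabilities (perfect, almost, moderate, low; remainder "none") for
category-concordant code pairs; per-arm target certainty distributions; and
a seed. The default design *is* the study condition: π = (42, 7, 2, 3, 0)/54,
C from the observed conditional rows, depth = (24, 8, 4, 3, 9)/48 — the
24/8 split of "perfect or almost perfect" is this package's choice, since
the published tables only report the merged count — and certainty targets
low/moderate/high+very-high of 3/7/44 (CDA, of 54) and 4/11/37 (MIA, of 52
conclusive), with the high vs very-high split, also unpublished, set near
even (22/22 and 19/18).

Codes are synthesized from the block table, not a full WHO code catalogue:
a pair at depth *d* picks a block/category and perturbs the appropriate
character. When a requested depth is structurally impossible for a category
under the map — "none" needs two chapters mapped to the same category, and
e.g. malignant lives entirely in chapter II — the generator degrades to the
nearest feasible deeper level (none → low → moderate → almost → perfect).
Consequently the pooled depth distribution matches `depth_agreement`
exactly only for categories spanning several chapters (infectious, other);
the goodness-of-fit test uses an infectious-only design for that reason.
Evidence grades are drawn by first sampling the target certainty, then a
uniform cell among the matrix cells with that certainty (rejection-free by
precomputed inversion). Nonconclusive arms get grade (0, 0).

`analytic_kappa` gives the closed-form kappa of the design's joint
distribution; tests verify the estimator recovers it (mean over 500
replicates at n = 54 within 3 Monte-Carlo SEs, and a single n = 100,000
run within 3 SEs). Generation is byte-deterministic under a fixed seed.

## Problem sizes and numerical choices

Simulation sizes in the test suite (500 replicates at n = 54; one run at
n = 100,000; goodness-of-fit at n = 10,000; CI coverage at 10,000
replicates of Binomial(20, p)) were chosen to keep Monte-Carlo error well
below the tolerances being asserted while the whole suite runs in about two
minutes. z = 1.959963984540054 is used for 95% intervals. Kappa is refused
when expected agreement is 1 (degenerate marginals) and CI bounds are
clipped to [−1, 1]. Certainty cross-checks on input CSVs (a supplied
`*_certainty` column disagreeing with the grade-derived level) are errors
in strict mode, warnings otherwise.

## Limitations

* The example series is margin-exact but case-synthetic (see above).
* The generator does not model postmortem-interval effects on microbial
  recovery, verbal-autopsy inputs, or within-case correlation between
  evidence grades and code-agreement depth; passing recovery tests show
  the estimator tracks the design's agreement structure, not that real
  paired-autopsy data behave like the generator.
* No weighted or multi-rater kappa, no bootstrap CIs; ICD-11 and clinical
  modifications (ICD-10-CM) are out of scope.
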