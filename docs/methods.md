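# Methods

`immex` implements an integrative procedure for nominating
tumor-intrinsic pathways associated with immune exclusion — the
absence of the T cell-inflamed tumor microenvironment — from bulk and
single-cell transcriptomes, together with the clinical-trial response
summaries used to evaluate therapies targeting a nominated pathway
(p38/MAPK14). This note records the models, the defaults and why they
are what they are, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was open.

## Signature scoring and stratification

The T cell-inflamed (TCI) score of a sample is the unweighted mean of
the normalized, log-scale expression of a signature gene set (the
validated 160-gene TCI signature is the intended input; the package
ships only a clearly labelled synthetic placeholder, because the gene
list is external input, not package data). Tumors are stratified into
non-inflamed / intermediate / inflamed by quantiles of the score —
tertiles by default, configurable, since the original two-tier
protocol is defined in prior work rather than restated here. With all
scores identical the split is undefined and every sample is classed
intermediate with a warning.

Pathway scores are means over a pathway's downstream target genes.
Two modes exist: the plain mean (default for bulk landscape scores)
and the direction-signed mean Σ s_g·x_g / N with s_g = +1 for
expected-up and −1 for expected-down targets (always used for
single-cell scores, where direction of regulation is part of the
published definition). Gene matching is exact and case-sensitive for
determinism.

## Bulk activation statistics

Causal-network pathway discovery from a commercial knowledge base is
out of scope; pathway definitions (regulator plus signed targets) are
inputs in a directional GMT dialect. The activation statistic is the
published concordance z: for each target, the non-inflamed minus
inflamed group mean difference d_g is compared with the expected sign
s_g, and

    z = Σ_g sign(d_g)·s_g / √N

over the N targets present, so |z| ≤ √N, z = √N under full
concordance and 0 under balance. The accompanying p-value is a
two-sided Welch test on the per-sample signed pathway score (a
documented stand-in for a limma-voom contrast, which is external
software). A pathway is called activated at z ≥ 1.95 and p < 0.05,
the printed thresholds.

Per-sample activation calls use the median rule: a target is
upregulated when its direction-adjusted value strictly exceeds the
direction-adjusted cohort median of that gene, and a sample is called
active when at least 50% (inclusive) of targets are upregulated.
Strict inequality at the median makes the call deterministic on
discrete data; ties do not count.

## Single-cell contrasts

Cells carry tumor (patient), cell type and malignant-flag
annotations; no clustering or cell-type inference is performed —
annotations are inputs, as in the cohorts this emulates. Tumors enter
the contrast only with ≥ 40 malignant cells and ≥ 100 cells total
(both inclusive). The per-tumor T cell fraction is the share of cells
annotated with a configurable T-cell label set (default {"T cell",
"Tcell", "T"}) among all cells sequenced.

Tumors are split into low/high infiltration groups at a quantile of
the fraction (median by default; a top/bottom-k extreme mode is
available). The quantile split is rank-based — the ceil(q·n) tumors
of lowest fraction are "low" — which coincides with thresholding at
the quantile for distinct fractions but cannot produce an empty or
size-one group when realized fractions tie at the cutoff, a real
occurrence at a few hundred cells per tumor.

Group contrasts of per-cell pathway scores use a linear mixed model
fitted by maximum likelihood (not REML): group as fixed effect, tumor
as random intercept, and a 1-df chi-square likelihood ratio test
against the model without the group effect. The reported estimate is
the fitted low-minus-high mean difference in log units. Cell-type
dominance contrasts use the nested design with random intercepts for
tumor and cell type within tumor. A singular fit (between-tumor
variance at zero) falls back to the equivalent OLS contrast and is
flagged in the output, never silent. Across a pathway family,
p-values receive Benjamini–Hochberg FDR correction and significance
is called at q < 0.10.

Numerically, each ML fit tries a cascade of optimizers (L-BFGS,
BFGS, Powell) and keeps the converged fit with the highest finite
log-likelihood: no single scipy optimizer proved reliable across
balanced toy problems and unbalanced cohort-scale data (one can
collapse the random-effect variance to zero with a divergent
likelihood, another can stop short of the optimum). Fits validated
against lme4 agree in estimate and LRT p to at least six decimals.

A small-sample caveat is documented rather than hidden: the
chi-square reference of the LRT is asymptotic in the number of
tumors, and at the five-tumor scale of the extreme-phenotype design
the test is somewhat anticonservative. The calibration suite
therefore checks the nominal type-I error on 60-tumor cohorts, where
the approximation holds, while recovery experiments keep the
five-tumor design.

## Prioritization

Three evidence streams are integrated per pathway: discovery-cohort
activation z (higher better), validation-cohort correlation of the
pathway score with TCI expression (more negative better), and the
single-cell contrast p-value (smaller better; an effect-size mode is
provided because the published text is ambiguous about which the
third rank used — p-value is the default, matching the figure
caption). Each stream maps to a relative rank: average-tie rank
position divided by N, so the best pathway gets 1/N and the worst 1.
The combined rank is the geometric mean of the three, which lies
between their min and max. A pathway is nominated when combined
< 0.6 **and** the maximum pairwise rank difference < 0.3 — both
strict, as printed, so a record at exactly 0.6 or 0.3 fails.
Pathways missing from a stream are a hard error by default; an
opt-in flag imputes the worst rank instead, because silent imputation
hides data misalignment.

## Pan-cancer p38 activation score

The packaged 12-gene p38 activation signature (ARG2, CD55, CYP4F3,
FST, GCLC, IL1A, MIF, PLA2G4A, PTGS2, S100A12, SLC6A2, VEGFA) is
scored on per-tumor expression — for single-cell cohorts, the
pseudobulk mean over malignant cells per tumor, the documented
default since the aggregation rule from cells to tumor specimens is
otherwise unspecified. Each gene is centered and scaled to unit
variance (ddof = 1) across tumors and the score is the per-tumor
mean of scaled values, so the cohort mean score is exactly zero;
zero-variance genes are dropped with a warning.

## Clinical summaries

Best overall response uses the printed thresholds: −100% complete
response, ≤ −30% partial response, ≥ +20% progressive disease,
otherwise stable — boundaries inclusive per RECIST convention.
Response confirmation (two scans ≥ 4 weeks apart) is caller-supplied
per subject, not computed, since per-subject scan tables are inputs.
Clinical benefit is strictly beyond the 6-month cutoff
(configurable). Rates are computed over evaluable subjects only and
rounded to one decimal, half away from zero, matching the printed
style. Survival uses the Kaplan–Meier product-limit estimator with
right censoring (censored times reduce the risk set without steps).

## Synthetic cohorts

The generator exists so every stage is testable with planted,
recoverable ground truth and no downloads. Its defaults are fixed
study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| per-gene baseline μ_g | Normal(5, 1) log2 units | arbitrary but fixed; typical normalized log-expression scale |
| cell/sample noise sd | 0.5 log2 units | realistic residual spread for log-scale scores |
| per-tumor random intercept sd | 0.1 log2 units | modest inter-patient offset; keeps the 5-tumor contrast estimable |
| T cell fraction range | Uniform(0.02, 0.40) | spread of low-to-moderate infiltration seen in the emulated cohorts |
| inflamed fraction (bulk) | 0.36 | discovery-cohort phenotype split |
| TCI shift in inflamed tumors | +2 log2 | clear phenotype separation |
| cell-type mixture | malignant 0.50, T 0.15, fibroblast 0.15, B 0.10, macrophage 0.10 | carcinoma-like TME composition; T proportion replaced per tumor by the drawn fraction |
| response mixture | (0.2, 0.4, 0.4) responder/stable/progressor | plausible refractory-population mix |

Planted pathways shift their up-targets +Δ and down-targets −Δ in
non-inflamed bulk tumors and in malignant cells of low-infiltration
single-cell tumors. The generator samples cell types first and
defines the low group by the rank-median split of the *realized* T
cell fractions — the same rule the analysis stage applies — because
at a few hundred cells per tumor, binomial sampling can reorder
tumors whose drawn fractions nearly tie, which would make ground
truth defined on drawn fractions unrecoverable in principle. Expression is simulated directly on the normalized log
scale — no count layer, no UMI sampling, no doublets or ambient RNA,
no gene–gene correlation beyond the planted shifts and tumor
intercepts. Passing recovery tests therefore demonstrates that the
statistical machinery recovers direction-aware planted signal at
realistic noise, not that it is robust to the full technical
structure of real single-cell data. All randomness flows through
NumPy's PCG64 `default_rng`; a fixed seed reproduces outputs
bit-for-bit.

## Problem sizes in the validation suites

Recovery experiments use 20 seed-swept cohorts of 5 tumors × 300
cells with Δ = 1.5 and a 10-pathway family (one planted), plus
60-tumor bulk cohorts for the bulk and anti-correlation streams.
Null calibration uses 500 Δ = 0 cohorts of 60 tumors × 20 cells.
These sizes were chosen so the chi-square reference of the LRT is
valid where calibration is asserted (see the caveat above) while the
recovery design matches the extreme-phenotype scale of the emulated
analysis.

## Known limitations

- The LRT is anticonservative at very few tumors (see above); at the
  5-tumor scale q-values should be read as rankings more than exact
  error rates.
- Pathway definitions and the 160-gene TCI signature are inputs; the
  package ships only the 12-gene p38 signature and synthetic
  placeholders.
- Bulk activation p-values come from a Welch contrast on signed
  scores, a simpler stand-in for precision-weighted regression; with
  few samples per class the two can disagree.
- The synthetic generator's independence assumptions make planted
  effects easier to detect than correlated real-data effects of the
  same size.
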