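"""Single-cell stage: per-cell pathway scores and infiltration contrasts.

Cells carry log-normalized expression plus three annotations: the
tumor (patient) they come from, a cell-type label, and a malignant
flag.  The stage mirrors the published analysis design:

1. score each pathway in each cell as the direction-signed mean of
   its target genes;
2. keep tumors with >=40 malignant cells and >=100 cells total;
3. rank tumors by T cell fraction (T cells / all cells sequenced) and
   split them into low- and high-infiltration groups;
4. contrast malignant-cell pathway scores between groups with a
   linear mixed model — group as fixed effect, tumor as random
   intercept, fitted by maximum likelihood — and a 1-df likelihood
   ratio test, followed by Benjamini-Hochberg FDR across pathways
   (significant at q < 0.10);
5. test cell-type dominance (e.g. malignant vs fibroblast) with a
   nested random-effects design (cell type within tumor);
6. compute the pan-cancer 12-gene p38 activation score on per-tumor
   pseudobulk: gene-wise center/scale across tumors, then per-tumor
   mean over the signature genes.

Model fits use :mod:`statsmodels` MixedLM with ``reml=False``; a
singular fit (zero between-tumor variance) falls back to an ordinary
least-squares contrast and is flagged, never silent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .bulk import ExpressionMatrix
from .signatures import GeneSignature, PathwayDefinition

logger = logging.getLogger(__name__)

#: Default annotation tokens treated as T cells; published cohorts
#: differ in their labels, so this set is configurable everywhere.
DEFAULT_TCELL_LABELS = frozenset({"T cell", "Tcell", "T"})

MIN_MALIGNANT_CELLS = 40
MIN_TOTAL_CELLS = 100
FDR_THRESHOLD = 0.10

REQUIRED_ANNOTATIONS = ("tumor_name", "cell_type", "is_malignant")


@dataclass
class CellCohort:
    """Cells x genes log-normalized expression with per-cell annotations.

    ``values`` is indexed by cell id with gene columns; ``annotations``
    shares the index and must provide ``tumor_name`` (non-empty str),
    ``cell_type`` (str) and ``is_malignant`` (bool).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate cell ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate gene ids")
        for col in REQUIRED_ANNOTATIONS:
            if col not in self.annotations.columns:
                raise ValueError(f"annotations missing column {col!r}")
        missing = self.values.index.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"cells without annotation: {list(missing)[:5]}")
        self.annotations = self.annotations.loc[self.values.index]
        if (self.annotations["tumor_name"].astype(str) == "").any():
            raise ValueError("empty tumor_name annotation")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.annotations = self.annotations.assign(
            is_malignant=self.annotations["is_malignant"].astype(bool)
        )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def tumors(self) -> list[str]:
        return sorted(self.annotations["tumor_name"].unique())

    def subset_cells(self, mask: pd.Series | np.ndarray) -> "CellCohort":
        return CellCohort(values=self.values.loc[mask],
                          annotations=self.annotations.loc[mask])

    def subset_tumors(self, tumors: Sequence[str]) -> "CellCohort":
        mask = self.annotations["tumor_name"].isin(set(tumors))
        return self.subset_cells(mask)

    def malignant(self) -> "CellCohort":
        return self.subset_cells(self.annotations["is_malignant"])

    # ---- I/O -------------------------------------------------------

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 annotations_path: str | Path) -> "CellCohort":
        """Read a cells-x-genes TSV plus an annotation TSV keyed by cell id."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        return cls(values=values, annotations=ann)

    @classmethod
    def from_mtx(cls, mtx_path: str | Path, genes_path: str | Path,
                 barcodes_path: str | Path,
                 annotations_path: str | Path) -> "CellCohort":
        """Read a 10x-style matrix-market triplet (genes x cells) cohort."""
        from scipy.io import mmread
        mat = mmread(str(mtx_path)).toarray().T  # cells x genes
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
        values = pd.DataFrame(mat, index=cells, columns=genes, dtype=float)
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        return cls(values=values, annotations=ann)

    def to_tsv(self, matrix_path: str | Path,
               annotations_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.annotations.to_csv(annotations_path, sep="\t")

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad
        return ad.AnnData(X=self.values.to_numpy(dtype=float),
                          obs=self.annotations.copy(),
                          var=pd.DataFrame(index=self.values.columns))

    @classmethod
    def from_anndata(cls, adata) -> "CellCohort":
        values = pd.DataFrame(np.asarray(adata.X, dtype=float),
                              index=adata.obs_names, columns=adata.var_names)
        return cls(values=values, annotations=adata.obs.copy())


@dataclass
class InfiltrationAssignment:
    """Per-tumor T cell fraction and low/high/excluded group label."""

    fraction: pd.Series
    group: pd.Series  # values in {"low", "high", "excluded"}
    split_rule: str = "median"

    def tumors_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])


@dataclass
class LmmContrast:
    """One mixed-model group contrast."""

    estimate: float      # low-minus-high (or typeA-minus-typeB) difference
    p: float             # 1-df likelihood-ratio test p-value
    fallback_ols: bool = False


@dataclass
class GroupComparison:
    """Per-pathway low-vs-high contrast with family-wise FDR."""

    pathway: str
    estimate: float
    p: float
    q: float
    significant: bool
    fallback_ols: bool = False


def pathway_score_cells(cohort: CellCohort,
                        pw: PathwayDefinition) -> pd.Series:
    """Per-cell pathway score: signed mean over the pathway's targets.

    Each present target contributes s_g * x_g with s_g = +1 for
    expected-up and -1 for expected-down targets, so direction of
    regulation is taken into account.
    """
    cols = set(cohort.values.columns)
    present = [g for g in pw.genes if g in cols]
    if not present:
        raise ValueError(f"pathway {pw.regulator!r}: no targets in cohort genes")
    if len(present) < len(pw):
        logger.warning("pathway %s: %d/%d targets absent",
                       pw.regulator, len(pw) - len(present), len(pw))
    signs = pw.signs()
    w = np.array([signs[g] for g in present], dtype=float)
    return (cohort.values[present] * w).mean(axis=1).rename(pw.regulator)


def filter_tumors(cohort: CellCohort,
                  min_malignant: int = MIN_MALIGNANT_CELLS,
                  min_total: int = MIN_TOTAL_CELLS) -> list[str]:
    """Tumors with >=``min_malignant`` malignant cells and >=``min_total`` total.

    Both bounds are inclusive.  Excluded tumors are logged; an empty
    result is allowed (with a warning).
    """
    ann = cohort.annotations
    total = ann.groupby("tumor_name").size()
    malig = ann.groupby("tumor_name")["is_malignant"].sum()
    kept: list[str] = []
    for tumor in total.index:
        if malig[tumor] >= min_malignant and total[tumor] >= min_total:
            kept.append(tumor)
        else:
            logger.info("tumor %s excluded (%d malignant, %d total)",
                        tumor, malig[tumor], total[tumor])
    if not kept:
        logger.warning("no tumors pass the %d/%d cell filters",
                       min_malignant, min_total)
    return sorted(kept)


def tcell_fraction(cohort: CellCohort,
                   tcell_labels: frozenset[str] | set[str] = DEFAULT_TCELL_LABELS,
                   ) -> pd.Series:
    """Per-tumor fraction of cells annotated as T cells, over all cells."""
    ann = cohort.annotations
    is_t = ann["cell_type"].isin(set(tcell_labels))
    if not is_t.any():
        logger.warning("no cells match T cell labels %s", sorted(tcell_labels))
    frac = is_t.groupby(ann["tumor_name"]).mean()
    return frac.rename("tcell_fraction").sort_index()


def assign_infiltration_groups(fractions: pd.Series, split: float = 0.5,
                               extremes_k: int | None = None,
                               ) -> InfiltrationAssignment:
    """Split tumors into low/high T cell infiltration groups.

    Default is a quantile split: the ceil(``split`` * n) tumors of
    lowest fraction are low, the rest high (rank-based, so a tie at
    the cutoff cannot empty a group; with distinct fractions this is
    the same as thresholding at the split quantile).  With
    ``extremes_k`` set, only the bottom-k (low) and top-k (high)
    tumors are labelled; the rest are excluded — the
    extreme-phenotype design.
    """
    if len(fractions) < 2:
        raise ValueError("need >=2 tumors to assign groups")
    vals = fractions.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError(
            "all T cell fractions equal; supply an explicit assignment"
        )
    order = fractions.sort_values(kind="mergesort").index
    if extremes_k is not None:
        if extremes_k < 1 or 2 * extremes_k > len(fractions):
            raise ValueError("extremes_k must satisfy 1 <= k <= n/2")
        group = pd.Series("excluded", index=fractions.index, dtype=object)
        group.loc[order[:extremes_k]] = "low"
        group.loc[order[-extremes_k:]] = "high"
        rule = f"extremes_k={extremes_k}"
    else:
        if not 0 < split < 1:
            raise ValueError("split quantile must lie in (0, 1)")
        n_low = min(len(fractions) - 1,
                    int(np.ceil(split * len(fractions))))
        group = pd.Series("high", index=fractions.index, dtype=object)
        group.loc[order[:n_low]] = "low"
        rule = f"quantile={split}"
    return InfiltrationAssignment(fraction=fractions, group=group,
                                  split_rule=rule)


def _lrt_p(llf_full: float, llf_null: float, df: int = 1) -> float:
    lrt = max(0.0, 2.0 * (llf_full - llf_null))
    return float(stats.chi2.sf(lrt, df))


#: optimizer cascade for ML mixed-model fits; no single scipy optimizer
#: is reliable across balanced/unbalanced toy-to-cohort scales
_FIT_METHODS = ("lbfgs", "bfgs", "powell")


def _fit_ml(model):
    """Fit a MixedLM by ML, trying optimizers until one yields a valid fit.

    Returns the converged finite-likelihood fit with the highest
    log-likelihood, or None if every optimizer fails (treated as a
    singular fit by callers).
    """
    best = None
    for method in _FIT_METHODS:
        try:
            res = model.fit(reml=False, method=method, maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(res.llf):
            continue
        if best is None or res.llf > best.llf + 1e-10:
            best = res
    return best


def compare_groups_lmm(scores: Sequence[float], groups: Sequence[str],
                       tumor_ids: Sequence[str]) -> LmmContrast:
    """Mixed-model low-vs-high contrast of per-cell scores.

    Fits ``score ~ 0 + group`` with a per-tumor random intercept by
    maximum likelihood and compares against the null model without
    the group effect via a 1-df chi-square likelihood ratio test.
    The estimate is the fitted low-group mean minus the high-group
    mean.  A singular fit (between-tumor variance collapsing to zero)
    or non-convergence falls back to the equivalent OLS contrast,
    flagged in the result.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "group": pd.Categorical(groups, categories=["low", "high"]),
        "tumor": np.asarray(tumor_ids, dtype=object),
    })
    if df["group"].isna().any():
        raise ValueError("groups must be 'low' or 'high'")
    per_group = df.groupby("group", observed=True)["tumor"].nunique()
    if (per_group < 2).any() or len(per_group) < 2:
        raise ValueError("need >=2 tumors in each group")
    mixed = df.groupby("tumor")["group"].nunique()
    if (mixed > 1).any():
        raise ValueError("each tumor's cells must share one group label")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit_ml(smf.mixedlm("score ~ 0 + C(group)", df,
                                   groups=df["tumor"]))
        null = _fit_ml(smf.mixedlm("score ~ 1", df, groups=df["tumor"]))
        singular = (full is None or null is None
                    or float(full.cov_re.iloc[0, 0]) < 1e-8)
    if not singular:
        coefs = full.fe_params
        est = float(coefs["C(group)[low]"] - coefs["C(group)[high]"])
        return LmmContrast(estimate=est, p=_lrt_p(full.llf, null.llf),
                           fallback_ols=False)

    logger.warning("singular mixed-model fit; falling back to OLS contrast")
    ols_full = smf.ols("score ~ 0 + C(group)", df).fit()
    ols_null = smf.ols("score ~ 1", df).fit()
    est = float(ols_full.params["C(group)[low]"]
                - ols_full.params["C(group)[high]"])
    return LmmContrast(estimate=est, p=_lrt_p(ols_full.llf, ols_null.llf),
                       fallback_ols=True)


def compare_groups_all(cohort: CellCohort,
                       pathways: Sequence[PathwayDefinition],
                       assignment: InfiltrationAssignment,
                       malignant_only: bool = True,
                       fdr_threshold: float = FDR_THRESHOLD,
                       ) -> list[GroupComparison]:
    """Low-vs-high mixed-model contrast for every pathway, with BH-FDR.

    Scores are computed on malignant cells by default.  The BH
    correction runs across the successfully fitted pathway family;
    pathways that fail to fit are reported via logging and omitted.
    Significance is called at q < ``fdr_threshold``.
    """
    if not list(pathways):
        return []
    low = set(assignment.tumors_in("low"))
    high = set(assignment.tumors_in("high"))
    if not low or not high:
        raise ValueError("assignment must contain both low and high tumors")
    sub = cohort.subset_tumors(low | high)
    if malignant_only:
        sub = sub.malignant()
    ann = sub.annotations
    groups = ann["tumor_name"].map(
        lambda t: "low" if t in low else "high").to_numpy()
    tumor_ids = ann["tumor_name"].to_numpy()

    fitted: list[tuple[str, LmmContrast]] = []
    for pw in pathways:
        try:
            scores = pathway_score_cells(sub, pw).to_numpy()
            fitted.append((pw.regulator, compare_groups_lmm(
                scores, groups, tumor_ids)))
        except ValueError as exc:
            logger.warning("pathway %s dropped from contrast: %s",
                           pw.regulator, exc)
    if not fitted:
        return []
    pvals = np.array([c.p for _, c in fitted])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        GroupComparison(pathway=name, estimate=c.estimate, p=c.p,
                        q=float(q), significant=bool(q < fdr_threshold),
                        fallback_ols=c.fallback_ols)
        for (name, c), q in zip(fitted, qvals)
    ]


def compare_celltypes_nested(scores: Sequence[float],
                             cell_types: Sequence[str],
                             tumor_ids: Sequence[str],
                             type_a: str, type_b: str) -> LmmContrast:
    """Nested mixed-model contrast of two cell types' scores.

    Fits ``score ~ 0 + cell_type`` with random intercepts for tumor
    and for cell type nested within tumor (maximum likelihood), and a
    1-df LRT on the cell-type fixed effect.  The estimate is the
    type-A minus type-B fitted mean.  Used for dominance questions
    such as whether malignant cells, not fibroblasts, carry a
    pathway's expression.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "cell_type": np.asarray(cell_types, dtype=object),
        "tumor": np.asarray(tumor_ids, dtype=object),
    })
    df = df[df["cell_type"].isin([type_a, type_b])]
    for t in (type_a, type_b):
        n_tum = df.loc[df["cell_type"] == t, "tumor"].nunique()
        if n_tum == 0:
            raise ValueError(f"cell type {t!r} absent")
        if n_tum < 2:
            raise ValueError(f"cell type {t!r} present in <2 tumors")
    df["cell_type"] = pd.Categorical(df["cell_type"],
                                     categories=[type_a, type_b])
    vc = {"celltype": "0 + C(cell_type)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit_ml(smf.mixedlm("score ~ 0 + C(cell_type)", df,
                                   groups=df["tumor"], re_formula="1",
                                   vc_formula=vc))
        null = _fit_ml(smf.mixedlm("score ~ 1", df, groups=df["tumor"],
                                   re_formula="1", vc_formula=vc))
        ok = full is not None and null is not None
    if ok:
        coefs = full.fe_params
        est = float(coefs[f"C(cell_type)[{type_a}]"]
                    - coefs[f"C(cell_type)[{type_b}]"])
        return LmmContrast(estimate=est, p=_lrt_p(full.llf, null.llf),
                           fallback_ols=False)
    logger.warning("singular nested fit; falling back to OLS contrast")
    ols_full = smf.ols("score ~ 0 + C(cell_type)", df).fit()
    ols_null = smf.ols("score ~ 1", df).fit()
    est = float(ols_full.params[f"C(cell_type)[{type_a}]"]
                - ols_full.params[f"C(cell_type)[{type_b}]"])
    return LmmContrast(estimate=est, p=_lrt_p(ols_full.llf, ols_null.llf),
                       fallback_ols=True)


def pseudobulk_malignant(cohort: CellCohort) -> ExpressionMatrix:
    """Per-tumor pseudobulk: mean expression over malignant cells."""
    malig = cohort.malignant()
    if malig.n_cells == 0:
        raise ValueError("no malignant cells in cohort")
    pb = malig.values.groupby(malig.annotations["tumor_name"]).mean()
    pb.index.name = None
    return ExpressionMatrix(values=pb)


def p38_score_tumors(tumor_expr: ExpressionMatrix,
                     sig: GeneSignature) -> pd.Series:
    """Per-tumor activation score for a signature on pseudobulk/bulk input.

    Each present signature gene is centered and scaled to unit
    variance across tumors; the score is the per-tumor mean of the
    scaled values.  By construction the cohort mean score is zero.
    Zero-variance genes are dropped with a warning.
    """
    if tumor_expr.n_samples < 2:
        raise ValueError("need >=2 tumors to scale across samples")
    cols = set(tumor_expr.values.columns)
    present = [g for g in sig.genes if g in cols]
    if not present:
        raise ValueError(f"signature {sig.name!r}: no genes present")
    sub = tumor_expr.values[present]
    sd = sub.std(axis=0, ddof=1)
    keep = [g for g in present if sd[g] > 0]
    dropped = sorted(set(present) - set(keep))
    if dropped:
        logger.warning("signature %s: zero-variance genes dropped: %s",
                       sig.name, dropped)
    if not keep:
        raise ValueError(
            f"signature {sig.name!r}: all present genes have zero variance"
        )
    z = (sub[keep] - sub[keep].mean(axis=0)) / sd[keep]
    return z.mean(axis=1).rename(f"{sig.name}_score")
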