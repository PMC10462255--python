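"""Bulk-cohort scoring: T cell-inflamed stratification and pathway activation.

The bulk stage works on normalized, log-scale expression matrices
(samples x genes).  It provides:

* the T cell-inflamed (TCI) score — the unweighted mean of the
  signature genes' expression per sample — and a quantile-based
  three-class stratification (non-inflamed / intermediate / inflamed);
* per-sample pathway scores (mean over targets, optionally weighted by
  each target's expected direction);
* a concordance activation z-score contrasting two sample classes:
  for each target gene the group mean difference d_g is compared with
  the expected direction s_g, and z = sum(sign(d_g) * s_g) / sqrt(N)
  over the N targets present; activation is called at z >= 1.95 and a
  Welch-test p < 0.05 on the per-sample signed pathway score;
* ordinary least-squares regression of co-occurring activated-pathway
  counts on the TCI score, and continuous Pearson/Spearman correlation
  of pathway scores with the TCI score;
* a per-sample pathway activation call requiring at least 50% of
  targets to be upregulated relative to their cohort median
  (direction-adjusted, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature, PathwayDefinition

logger = logging.getLogger(__name__)

TCI_CLASSES = ("non_inflamed", "intermediate", "inflamed")

#: default activation thresholds, as printed in the source analysis
Z_THRESHOLD = 1.95
P_THRESHOLD = 0.05


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of normalized log-scale expression.

    ``values`` is a DataFrame indexed by sample id with gene-symbol
    columns.  ``metadata`` is an optional per-sample table aligned on
    the same index.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            raise ValueError("duplicate sample ids")
        if not v.columns.is_unique:
            raise ValueError("duplicate gene ids")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.metadata is not None:
            missing = v.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing samples: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_tsv(cls, path: str | Path, genes_as_rows: bool = True,
                 sep: str = "\t",
                 metadata_path: str | Path | None = None) -> "ExpressionMatrix":
        """Read a delimited expression table (gzip handled by suffix).

        By convention bulk matrices are distributed genes-as-rows; set
        ``genes_as_rows=False`` for samples-as-rows layouts.
        """
        df = pd.read_csv(path, sep=sep, index_col=0)
        if genes_as_rows:
            df = df.T
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep=sep, index_col=0)
        return cls(values=df.astype(float), metadata=meta)

    def to_tsv(self, path: str | Path, genes_as_rows: bool = True) -> None:
        df = self.values.T if genes_as_rows else self.values
        df.to_csv(path, sep="\t")


@dataclass
class TCIResult:
    """Per-sample T cell-inflamed scores and phenotype classes."""

    score: pd.Series
    klass: pd.Series  # values in TCI_CLASSES

    def class_fractions(self) -> dict[str, float]:
        n = len(self.klass)
        return {c: float((self.klass == c).sum()) / n for c in TCI_CLASSES}


@dataclass
class PathwayActivationResult:
    """Group-contrast activation statistics for one pathway."""

    pathway: str
    score: pd.Series          # per-sample signed pathway score
    zscore: float
    p: float
    activated: bool
    n_targets_used: int


def _present_genes(genes: Sequence[str], expr: ExpressionMatrix,
                   label: str) -> list[str]:
    cols = set(expr.values.columns)
    present = [g for g in genes if g in cols]
    missing = [g for g in genes if g not in cols]
    if missing:
        logger.warning("%s: %d/%d genes absent from matrix (e.g. %s)",
                       label, len(missing), len(genes), missing[:5])
    if not present:
        raise ValueError(f"{label}: no genes present in expression matrix")
    return present


def tci_score(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """T cell-inflamed score: per-sample mean of the signature genes.

    Computed as the unweighted mean of normalized, log-transformed
    expression over the signature genes present in the matrix.
    """
    present = _present_genes(sig.genes, expr, f"signature {sig.name}")
    return expr.values[present].mean(axis=1).rename(f"tci_{sig.name}")


def classify_tci(scores: pd.Series, lower_q: float = 1 / 3,
                 upper_q: float = 2 / 3) -> TCIResult:
    """Stratify samples into non-inflamed / intermediate / inflamed.

    Samples at or below the ``lower_q`` quantile of the score are
    non-inflamed, at or above ``upper_q`` inflamed, otherwise
    intermediate.  With every score identical the split is undefined
    and all samples are classed intermediate (with a warning).
    """
    if len(scores) < 3:
        raise ValueError("classification needs >=3 samples")
    if not 0 < lower_q < upper_q < 1:
        raise ValueError("quantiles must satisfy 0 < lower_q < upper_q < 1")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        logger.warning("degenerate scores (all equal): classing all intermediate")
        klass = pd.Series("intermediate", index=scores.index)
        return TCIResult(score=scores, klass=klass)
    lo, hi = np.quantile(vals, [lower_q, upper_q])
    klass = pd.Series(
        np.where(vals <= lo, "non_inflamed",
                 np.where(vals >= hi, "inflamed", "intermediate")),
        index=scores.index,
    )
    return TCIResult(score=scores, klass=klass)


def pathway_score_bulk(expr: ExpressionMatrix, pw: PathwayDefinition,
                       signed: bool = False) -> pd.Series:
    """Per-sample pathway score: mean expression of the pathway targets.

    With ``signed=True`` each target contributes s_g * x_g, where s_g
    is +1 for expected-up and -1 for expected-down targets.  The plain
    (unsigned) mean is the default for bulk landscape scores.
    """
    present = _present_genes(pw.genes, expr, f"pathway {pw.regulator}")
    sub = expr.values[present]
    if signed:
        signs = pw.signs()
        w = np.array([signs[g] for g in present], dtype=float)
        return (sub * w).mean(axis=1).rename(pw.regulator)
    return sub.mean(axis=1).rename(pw.regulator)


def activation_zscore(expr: ExpressionMatrix, pw: PathwayDefinition,
                      klass_a: Sequence[str], klass_b: Sequence[str],
                      z_threshold: float = Z_THRESHOLD,
                      p_threshold: float = P_THRESHOLD,
                      ) -> PathwayActivationResult:
    """Concordance activation z for class A relative to class B.

    For each present target g, d_g is the class-A minus class-B mean
    difference and s_g the expected direction sign; the concordance
    c_g = sign(d_g) * s_g and z = sum(c_g) / sqrt(N).  The p-value is
    a two-sided Welch test on the per-sample signed pathway score
    between the two classes.  The pathway is called activated in A at
    z >= ``z_threshold`` and p < ``p_threshold``.
    """
    a = list(klass_a)
    b = list(klass_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need >=2 samples")
    present = _present_genes(pw.genes, expr, f"pathway {pw.regulator}")
    signs = pw.signs()
    sub_a = expr.values.loc[a, present]
    sub_b = expr.values.loc[b, present]
    d = sub_a.mean(axis=0) - sub_b.mean(axis=0)
    s = np.array([signs[g] for g in present], dtype=float)
    conc = np.sign(d.to_numpy()) * s
    z = float(conc.sum() / np.sqrt(len(present)))
    score = pathway_score_bulk(expr, pw, signed=True)
    t_res = stats.ttest_ind(score.loc[a], score.loc[b], equal_var=False)
    p = float(t_res.pvalue)
    return PathwayActivationResult(
        pathway=pw.regulator, score=score, zscore=z, p=p,
        activated=bool(z >= z_threshold and p < p_threshold),
        n_targets_used=len(present),
    )


def cooccurrence_regression(tci: Sequence[float], n_activated: Sequence[float]
                            ) -> tuple[float, float, float]:
    """OLS of co-occurring activated-pathway count on TCI score.

    Returns (slope, R^2, slope p-value).  An inverse relationship
    (negative slope) indicates that less inflamed tumors carry more
    co-occurring activated pathways.
    """
    x = np.asarray(tci, dtype=float)
    y = np.asarray(n_activated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tci and n_activated must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("regression needs >=3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in tci scores")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def correlate_pathways_with_tci(
    expr: ExpressionMatrix,
    pathways: Sequence[PathwayDefinition],
    sig: GeneSignature,
    method: Literal["pearson", "spearman"] = "pearson",
    signed: bool = False,
) -> pd.DataFrame:
    """Continuous correlation of each pathway score with the TCI score.

    Returns a DataFrame indexed by pathway with columns ``r`` and
    ``p``.  A pathway whose score is constant has undefined
    correlation and is reported as NaN (with a warning); other
    pathways are unaffected.
    """
    if expr.n_samples < 3:
        raise ValueError("correlation needs >=3 samples")
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    tci = tci_score(expr, sig).to_numpy()
    rows = {}
    for pw in pathways:
        score = pathway_score_bulk(expr, pw, signed=signed).to_numpy()
        if np.ptp(score) == 0 or np.ptp(tci) == 0:
            logger.warning("pathway %s: constant vector, correlation undefined",
                           pw.regulator)
            rows[pw.regulator] = (np.nan, np.nan)
            continue
        res = corr(tci, score)
        rows[pw.regulator] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p"])


def pathway_activation_call(expr: ExpressionMatrix, pw: PathwayDefinition,
                            min_fraction: float = 0.5) -> pd.Series:
    """Per-sample boolean pathway activation call.

    A target counts as upregulated in a sample when its
    direction-adjusted value s_g * x_gs strictly exceeds the
    direction-adjusted cohort median of that gene; the pathway is
    called active when at least ``min_fraction`` (default 50%,
    inclusive) of present targets are upregulated.
    """
    if expr.n_samples < 2:
        raise ValueError("activation call needs >=2 samples for a cohort median")
    present = _present_genes(pw.genes, expr, f"pathway {pw.regulator}")
    signs = pw.signs()
    w = np.array([signs[g] for g in present], dtype=float)
    adj = expr.values[present].to_numpy() * w   # samples x targets
    med = np.median(adj, axis=0)
    frac_up = (adj > med).mean(axis=1)
    return pd.Series(frac_up >= min_fraction, index=expr.values.index,
                     name=pw.regulator)
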