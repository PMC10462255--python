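"""Synthetic cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure of the public
cohorts the pipeline is designed for, at a scale where every stage is
testable without any download:

* **bulk cohorts** — samples x genes log2-scale matrices with
  Gaussian noise around per-gene baselines, a T cell-inflamed gene
  shift in inflamed tumors, and direction-aware planted pathway
  shifts (up-targets +delta, down-targets -delta) in non-inflamed
  tumors;
* **single-cell cohorts** — per-tumor T cell fractions drawn from a
  configurable range, cell types sampled per cell with the T-cell
  proportion pinned to the drawn fraction, a per-tumor random
  intercept (inter-patient spread), and planted pathway shifts in
  malignant cells of low-infiltration tumors;
* **clinical response tables** — a responder / stable / progressor
  mixture with class-specific percent-change and benefit-duration
  distributions.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so
a fixed seed reproduces outputs bit-for-bit across runs and
platforms.  Low/high infiltration ground truth is assigned by the
rank-based median split of the realized T cell fractions — the same
rule the analysis stage applies — so the planted structure refers to
the data a downstream analyst can observe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bulk import ExpressionMatrix
from .clinical import SubjectResponse
from .signatures import GeneSignature, PathwayDefinition
from .singlecell import CellCohort

#: Default cell-type mixture before the T-cell proportion is replaced
#: by the per-tumor drawn fraction (non-T types are renormalized).
DEFAULT_CELLTYPE_PROPORTIONS: dict[str, float] = {
    "malignant": 0.50,
    "T cell": 0.15,
    "fibroblast": 0.15,
    "B cell": 0.10,
    "macrophage": 0.10,
}

BASELINE_MEAN = 5.0   # per-gene baseline location, log2 units
BASELINE_SD = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for all three generators.

    ``planted_pathways`` pairs each pathway definition with its
    effect size delta (log2 units): up-targets are shifted +delta and
    down-targets -delta in the affected tumors/cells.
    """

    seed: int = 0
    n_tumors: int = 60
    n_genes: int = 500
    frac_inflamed: float = 0.36
    planted_pathways: tuple[tuple[PathwayDefinition, float], ...] = ()
    noise_sd: float = 0.5
    cells_per_tumor: tuple[int, int] = (100, 300)
    celltype_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_PROPORTIONS))
    tcell_fraction_range: tuple[float, float] = (0.02, 0.40)
    tci_effect: float = 2.0
    tumor_effect_sd: float = 0.1
    gene_universe: tuple[str, ...] | None = None
    # clinical response table
    n_subjects: int = 100
    response_weights: tuple[float, float, float] = (0.2, 0.4, 0.4)

    def __post_init__(self) -> None:
        props = dict(self.celltype_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("celltype proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ValueError("celltype proportions must be nonnegative")
        if not 0 <= self.frac_inflamed <= 1:
            raise ValueError("frac_inflamed must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tumor_effect_sd < 0:
            raise ValueError("tumor_effect_sd must be nonnegative")
        lo, hi = self.tcell_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("tcell_fraction_range must be within [0, 1]")
        for pw, delta in self.planted_pathways:
            if not np.isfinite(delta):
                raise ValueError(f"effect size for {pw.regulator} not finite")
        if abs(sum(self.response_weights) - 1.0) > 1e-9:
            raise ValueError("response_weights must sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    inflamed_class: pd.Series | None = None      # bulk: per-tumor bool
    tcell_fraction: pd.Series | None = None      # sc: per-tumor fraction
    infiltration_group: pd.Series | None = None  # sc: low/high by median
    planted_pathways: tuple[str, ...] = ()
    gene_shift: dict[str, float] = field(default_factory=dict)


def placeholder_tci_signature(n_genes: int = 160) -> GeneSignature:
    """Synthetic stand-in for the 160-gene T cell-inflamed signature.

    The validated gene list is an external input to the pipeline;
    this placeholder (symbols ``TCI001``...) exists so generated
    cohorts can exercise the scoring path end to end.
    """
    return GeneSignature(
        name="TCI_PLACEHOLDER",
        genes=tuple(f"TCI{i + 1:03d}" for i in range(n_genes)),
    )


def make_pathways(n_pathways: int, n_targets: int = 10, n_down: int = 3,
                  prefix: str = "PW") -> list[PathwayDefinition]:
    """Deterministic synthetic pathway definitions over fresh gene names.

    Each pathway gets ``n_targets`` unique targets, the last
    ``n_down`` expected-down; gene names are disjoint across pathways.
    """
    if not 0 <= n_down <= n_targets:
        raise ValueError("n_down must lie in [0, n_targets]")
    out = []
    for i in range(n_pathways):
        targets = tuple(
            (f"{prefix}{i + 1:02d}G{j + 1:02d}",
             "down" if j >= n_targets - n_down else "up")
            for j in range(n_targets)
        )
        out.append(PathwayDefinition(regulator=f"{prefix}{i + 1:02d}",
                                     targets=targets, source="synthetic"))
    return out


def _build_universe(config: SyntheticConfig,
                    required: Sequence[str]) -> list[str]:
    required = list(dict.fromkeys(required))
    if config.gene_universe is not None:
        universe = list(config.gene_universe)
        missing = sorted(set(required) - set(universe))
        if missing:
            raise ValueError(f"genes missing from universe: {missing}")
        return universe
    n_filler = max(0, config.n_genes - len(required))
    filler = [f"G{i + 1:05d}" for i in range(n_filler)]
    return required + filler


def _pathway_shifts(planted: Sequence[tuple[PathwayDefinition, float]]
                    ) -> dict[str, float]:
    shifts: dict[str, float] = {}
    for pw, delta in planted:
        for gene, sign in pw.signs().items():
            shifts[gene] = shifts.get(gene, 0.0) + sign * delta
    return shifts


def generate_bulk_cohort(config: SyntheticConfig,
                         tci_signature: GeneSignature,
                         ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Bulk cohort with inflamed-class and planted-pathway structure.

    Baseline expression is Normal(mu_g, noise_sd) on the log2 scale
    with mu_g ~ Normal(5, 1) drawn once per gene.  Inflamed tumors
    have the T cell-inflamed signature genes shifted +``tci_effect``;
    non-inflamed tumors carry each planted pathway's direction-aware
    shift.
    """
    rng = np.random.default_rng(config.seed)
    pathway_genes = [g for pw, _ in config.planted_pathways for g in pw.genes]
    universe = _build_universe(config, list(tci_signature.genes) + pathway_genes)
    n, g = config.n_tumors, len(universe)
    if n < 2:
        raise ValueError("need >=2 tumors")

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g)
    values = mu + rng.normal(0.0, config.noise_sd, size=(n, g))

    n_inflamed = int(round(config.frac_inflamed * n))
    inflamed = np.zeros(n, dtype=bool)
    inflamed[rng.permutation(n)[:n_inflamed]] = True

    gene_pos = {gene: j for j, gene in enumerate(universe)}
    tci_idx = [gene_pos[gene] for gene in tci_signature.genes]
    values[np.ix_(inflamed, tci_idx)] += config.tci_effect

    shifts = _pathway_shifts(config.planted_pathways)
    for gene, shift in shifts.items():
        values[~inflamed, gene_pos[gene]] += shift

    samples = [f"T{i + 1:03d}" for i in range(n)]
    expr = ExpressionMatrix(values=pd.DataFrame(values, index=samples,
                                                columns=universe))
    truth = GroundTruth(
        inflamed_class=pd.Series(inflamed, index=samples, name="inflamed"),
        planted_pathways=tuple(pw.regulator
                               for pw, _ in config.planted_pathways),
        gene_shift=shifts,
    )
    return expr, truth


def generate_sc_cohort(config: SyntheticConfig,
                       ) -> tuple[CellCohort, GroundTruth]:
    """Single-cell cohort with low/high infiltration ground truth.

    Per tumor, a T cell fraction is drawn uniformly from
    ``tcell_fraction_range`` and cell types are sampled per cell with
    the T-cell proportion pinned to that fraction (other types
    renormalized).  Ground-truth low/high groups come from the
    rank-based median split of the *realized* T cell fractions — the
    same rule :func:`immex.singlecell.assign_infiltration_groups`
    applies downstream — so the planted structure refers to the data
    a scientist can actually observe (at few hundred cells per tumor
    the realized fraction can reorder tumors whose drawn fractions
    nearly tie).  Malignant cells of low-group tumors carry the
    planted pathway shifts.  Expression adds a per-tumor Normal(0,
    tumor_effect_sd) intercept to Gaussian cell-level noise.
    """
    from .singlecell import assign_infiltration_groups

    rng = np.random.default_rng(config.seed)
    lo, hi = config.cells_per_tumor
    if lo < 1:
        raise ValueError("cells_per_tumor must be >=1")
    pathway_genes = [g for pw, _ in config.planted_pathways for g in pw.genes]
    universe = _build_universe(config, pathway_genes)
    gene_pos = {gene: j for j, gene in enumerate(universe)}

    props = dict(config.celltype_proportions)
    other_types = [t for t in props if t != "T cell"]
    other_total = sum(props[t] for t in other_types)
    if other_total <= 0:
        raise ValueError("need at least one non-T cell type")

    tumors = [f"S{i + 1:02d}" for i in range(config.n_tumors)]
    drawn = pd.Series(
        rng.uniform(config.tcell_fraction_range[0],
                    config.tcell_fraction_range[1], size=config.n_tumors),
        index=tumors, name="tcell_fraction",
    )

    # sample cell types first so grouping can use realized fractions
    types_by_tumor: dict[str, np.ndarray] = {}
    for tumor in tumors:
        n_cells = int(rng.integers(lo, hi + 1))
        f = float(drawn[tumor])
        p = np.array([f] + [props[t] * (1 - f) / other_total
                            for t in other_types])
        types_by_tumor[tumor] = rng.choice(["T cell"] + other_types,
                                           size=n_cells, p=p)
    fractions = pd.Series(
        {t: float(np.mean(types_by_tumor[t] == "T cell")) for t in tumors},
        name="tcell_fraction",
    )
    try:
        group = assign_infiltration_groups(fractions).group
    except ValueError:
        # realized fractions all tied (tiny cohorts): fall back to the
        # drawn-fraction ordering
        group = assign_infiltration_groups(drawn).group
    group = group.rename("infiltration_group")

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(universe))
    shifts = _pathway_shifts(config.planted_pathways)

    blocks, ann_rows, cell_ids = [], [], []
    for tumor in tumors:
        types = types_by_tumor[tumor]
        n_cells = len(types)
        tumor_intercept = rng.normal(0.0, config.tumor_effect_sd)
        block = (mu + tumor_intercept
                 + rng.normal(0.0, config.noise_sd,
                              size=(n_cells, len(universe))))
        malignant = types == "malignant"
        if group[tumor] == "low" and malignant.any():
            for gene, shift in shifts.items():
                block[malignant, gene_pos[gene]] += shift
        blocks.append(block)
        for k, ct in enumerate(types):
            cell_ids.append(f"{tumor}_C{k + 1:04d}")
            ann_rows.append((tumor, ct, bool(ct == "malignant")))

    values = pd.DataFrame(np.vstack(blocks), index=cell_ids, columns=universe)
    ann = pd.DataFrame(ann_rows, index=cell_ids,
                       columns=["tumor_name", "cell_type", "is_malignant"])
    cohort = CellCohort(values=values, annotations=ann)
    truth = GroundTruth(
        tcell_fraction=fractions,
        infiltration_group=group,
        planted_pathways=tuple(pw.regulator
                               for pw, _ in config.planted_pathways),
        gene_shift=shifts,
    )
    return cohort, truth


def generate_response_table(config: SyntheticConfig) -> list[SubjectResponse]:
    """Trial-style response table from a three-class mixture.

    Responders draw percent change from Uniform(-100, -30) and are
    irRECIST- and RECIST-confirmed; stable subjects from
    Uniform(-29, 19); progressors from Uniform(20, 100).  Benefit
    durations are Uniform(8, 30), (1, 12) and (0, 4) months per
    class; transition to new therapy within a year is flagged when
    benefit lasted 12 months or less.
    """
    if config.n_subjects < 1:
        raise ValueError("need >=1 subject")
    rng = np.random.default_rng(config.seed)
    classes = rng.choice(3, size=config.n_subjects,
                         p=list(config.response_weights))
    pct_ranges = [(-100.0, -30.0), (-29.0, 19.0), (20.0, 100.0)]
    benefit_ranges = [(8.0, 30.0), (1.0, 12.0), (0.0, 4.0)]
    rows = []
    for i, cls in enumerate(classes):
        pct = float(rng.uniform(*pct_ranges[cls]))
        benefit = float(rng.uniform(*benefit_ranges[cls]))
        rows.append(SubjectResponse(
            subject_id=f"SUBJ{i + 1:04d}",
            best_pct_change=pct,
            confirmed_recist=bool(cls == 0),
            confirmed_irrecist=bool(cls == 0),
            benefit_months=benefit,
            new_therapy_within_1yr=bool(benefit <= 12.0),
            evaluable=True,
        ))
    return rows


def write_sc_cohort(cohort: CellCohort, truth: GroundTruth,
                    outdir: str | Path) -> dict[str, Path]:
    """Write a generated single-cell cohort through the real I/O formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "cells_x_genes.tsv",
        "annotations": outdir / "cell_annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    cohort.to_tsv(paths["matrix"], paths["annotations"])
    _write_truth(truth, paths["ground_truth"])
    return paths


def write_bulk_cohort(expr: ExpressionMatrix, truth: GroundTruth,
                      outdir: str | Path) -> dict[str, Path]:
    """Write a generated bulk cohort (genes-as-rows TSV) plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    expr.to_tsv(paths["matrix"], genes_as_rows=True)
    _write_truth(truth, paths["ground_truth"])
    return paths


def _write_truth(truth: GroundTruth, path: Path) -> None:
    import json
    payload = {
        "planted_pathways": list(truth.planted_pathways),
        "gene_shift": truth.gene_shift,
    }
    if truth.inflamed_class is not None:
        payload["inflamed_class"] = {
            k: bool(v) for k, v in truth.inflamed_class.items()}
    if truth.tcell_fraction is not None:
        payload["tcell_fraction"] = {
            k: float(v) for k, v in truth.tcell_fraction.items()}
    if truth.infiltration_group is not None:
        payload["infiltration_group"] = dict(truth.infiltration_group)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
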