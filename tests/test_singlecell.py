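"""Single-cell scoring, filters, mixed-model contrasts, p38 score."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from immex.bulk import ExpressionMatrix
from immex.signatures import (GeneSignature, PathwayDefinition,
                              builtin_p38_signature)
from immex.singlecell import (CellCohort, assign_infiltration_groups,
                              compare_celltypes_nested, compare_groups_all,
                              compare_groups_lmm, filter_tumors,
                              p38_score_tumors, pathway_score_cells,
                              pseudobulk_malignant, tcell_fraction)
from immex.synthetic import SyntheticConfig, generate_sc_cohort, make_pathways


def _cohort(values, tumors, cell_types=None, malignant=None, genes=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    cells = [f"c{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    ann = pd.DataFrame({
        "tumor_name": tumors,
        "cell_type": cell_types or ["malignant"] * n,
        "is_malignant": malignant if malignant is not None
        else [ct == "malignant" for ct in (cell_types or ["malignant"] * n)],
    }, index=cells)
    return CellCohort(values=pd.DataFrame(values, index=cells, columns=genes),
                      annotations=ann)


def _counts_cohort(spec):
    """Cohort from {tumor: (n_malignant, n_other)} with trivial expression."""
    tumors, types = [], []
    for tumor, (n_mal, n_other) in spec.items():
        tumors += [tumor] * (n_mal + n_other)
        types += ["malignant"] * n_mal + ["T cell"] * n_other
    return _cohort(np.zeros((len(tumors), 2)), tumors, types)


class TestPathwayScoreCells:
    def test_all_up_constant(self):
        cohort = _cohort(np.full((3, 2), 1.5), ["t1"] * 3)
        pw = PathwayDefinition("P", (("g0", "up"), ("g1", "up")))
        assert np.allclose(pathway_score_cells(cohort, pw), 1.5)

    def test_up_down_cancellation(self):
        cohort = _cohort([[1.0, 1.0]], ["t1"])
        pw = PathwayDefinition("P", (("g0", "up"), ("g1", "down")))
        assert pathway_score_cells(cohort, pw).iloc[0] == pytest.approx(0.0)

    def test_matches_bruteforce_signed_mean(self, rng):
        cohort = _cohort(rng.normal(size=(200, 12)), ["t1"] * 200)
        targets = tuple((f"g{i}", "down" if i % 3 == 0 else "up")
                        for i in range(8))
        pw = PathwayDefinition("P", targets)
        signs = np.array([-1 if i % 3 == 0 else 1 for i in range(8)])
        expected = (cohort.values.iloc[:, :8].to_numpy() * signs).mean(axis=1)
        assert np.allclose(pathway_score_cells(cohort, pw), expected,
                           atol=1e-12)

    def test_linear_in_expression(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=(20, 5))
        pw = PathwayDefinition("P", tuple((f"g{i}", "up") for i in range(5)))
        sx = pathway_score_cells(_cohort(x, ["t"] * 20), pw)
        sy = pathway_score_cells(_cohort(y, ["t"] * 20), pw)
        sxy = pathway_score_cells(_cohort(x + y, ["t"] * 20), pw)
        assert np.allclose(sxy, sx.to_numpy() + sy.to_numpy(), atol=1e-12)

    def test_zero_overlap_names_pathway(self):
        cohort = _cohort(np.zeros((2, 2)), ["t"] * 2)
        with pytest.raises(ValueError, match="ABSENT"):
            pathway_score_cells(cohort, PathwayDefinition(
                "ABSENT", (("nope", "up"),)))


class TestFilterTumors:
    def test_malignant_bound_exclusive_below(self):
        kept = filter_tumors(_counts_cohort({"A": (39, 461)}))
        assert kept == []

    def test_boundary_40_100_kept(self):
        kept = filter_tumors(_counts_cohort({"A": (40, 60)}))
        assert kept == ["A"]

    def test_total_bound(self):
        kept = filter_tumors(_counts_cohort({"A": (99, 0)}))
        assert kept == []

    def test_mixed_cohort(self):
        kept = filter_tumors(_counts_cohort({
            "A": (40, 60), "B": (39, 500), "C": (200, 0)}))
        assert kept == ["A", "C"]


class TestTcellFraction:
    def test_arithmetic(self):
        cohort = _counts_cohort({"A": (75, 25)})
        assert tcell_fraction(cohort)["A"] == pytest.approx(0.25)

    def test_zero_tcells(self):
        cohort = _counts_cohort({"A": (10, 0)})
        assert tcell_fraction(cohort)["A"] == 0.0

    def test_cell_order_invariance(self, rng):
        cohort = _counts_cohort({"A": (30, 10), "B": (5, 15)})
        perm = list(rng.permutation(cohort.values.index))
        shuffled = CellCohort(values=cohort.values.loc[perm],
                              annotations=cohort.annotations.loc[perm])
        pd.testing.assert_series_equal(tcell_fraction(cohort),
                                       tcell_fraction(shuffled))


class TestAssignInfiltrationGroups:
    def test_median_split(self):
        frac = pd.Series([0.01, 0.05, 0.2, 0.4], index=list("abcd"))
        a = assign_infiltration_groups(frac)
        assert sorted(a.tumors_in("low")) == ["a", "b"]
        assert sorted(a.tumors_in("high")) == ["c", "d"]

    def test_extremes_mode(self):
        frac = pd.Series([0.5, 0.1, 0.3, 0.2, 0.4], index=list("abcde"))
        a = assign_infiltration_groups(frac, extremes_k=1)
        assert a.tumors_in("low") == ["b"]
        assert a.tumors_in("high") == ["a"]
        assert len(a.tumors_in("excluded")) == 3

    def test_all_equal_errors(self):
        with pytest.raises(ValueError, match="explicit"):
            assign_infiltration_groups(pd.Series([0.2, 0.2, 0.2]))

    def test_recovers_bimodal_ground_truth(self):
        """With well-separated fraction modes the split recovers membership."""
        lo_cfg = SyntheticConfig(seed=12, n_tumors=4, n_genes=30,
                                 cells_per_tumor=(400, 400),
                                 tcell_fraction_range=(0.02, 0.08))
        hi_cfg = SyntheticConfig(seed=13, n_tumors=4, n_genes=30,
                                 cells_per_tumor=(400, 400),
                                 tcell_fraction_range=(0.30, 0.40))
        lo, _ = generate_sc_cohort(lo_cfg)
        hi, _ = generate_sc_cohort(hi_cfg)
        hi_renamed = hi.annotations.assign(
            tumor_name="H" + hi.annotations["tumor_name"])
        hi = CellCohort(values=hi.values.set_axis(
            "H" + hi.values.index, axis=0),
            annotations=hi_renamed.set_axis("H" + hi_renamed.index, axis=0))
        merged = CellCohort(
            values=pd.concat([lo.values, hi.values]),
            annotations=pd.concat([lo.annotations, hi.annotations]))
        assignment = assign_infiltration_groups(tcell_fraction(merged))
        assert set(assignment.tumors_in("low")) == set(lo.tumors)
        assert set(assignment.tumors_in("high")) == set(hi.tumors)


class TestCompareGroupsLmm:
    def _planted(self, seed=0, delta=1.0, n_tumors=8, n_cells=40):
        pw = make_pathways(1)[0]
        cfg = SyntheticConfig(seed=seed, n_tumors=n_tumors, n_genes=30,
                              cells_per_tumor=(n_cells, n_cells),
                              planted_pathways=((pw, delta),))
        cohort, truth = generate_sc_cohort(cfg)
        malig = cohort.malignant()
        scores = pathway_score_cells(malig, pw).to_numpy()
        groups = malig.annotations["tumor_name"].map(
            dict(truth.infiltration_group)).to_numpy()
        tumors = malig.annotations["tumor_name"].to_numpy()
        return scores, groups, tumors

    def test_separation_estimate_and_p(self):
        scores = np.concatenate([np.full(40, 5.0), np.full(40, 0.0)]) \
            + np.tile(np.linspace(-1e-3, 1e-3, 40), 2)
        groups = ["low"] * 40 + ["high"] * 40
        tumors = (["t1"] * 20 + ["t2"] * 20 + ["t3"] * 20 + ["t4"] * 20)
        res = compare_groups_lmm(scores, groups, tumors)
        assert res.estimate == pytest.approx(5.0, abs=1e-2)
        assert res.p < 1e-10

    def test_invariant_to_cell_permutation_and_tumor_relabel(self, rng):
        scores, groups, tumors = self._planted(seed=13)
        base = compare_groups_lmm(scores, groups, tumors)
        perm = rng.permutation(len(scores))
        relabel = {t: f"X{t}" for t in set(tumors)}
        res = compare_groups_lmm(scores[perm], groups[perm],
                                 np.array([relabel[t] for t in tumors])[perm])
        assert res.p == pytest.approx(base.p, rel=1e-6)
        assert res.estimate == pytest.approx(base.estimate, rel=1e-6)

    def test_requires_two_tumors_per_group(self):
        with pytest.raises(ValueError, match="2 tumors"):
            compare_groups_lmm([1.0, 2.0, 3.0, 4.0],
                               ["low", "low", "high", "high"],
                               ["t1", "t1", "t2", "t2"])

    def test_rejects_tumor_spanning_groups(self):
        with pytest.raises(ValueError, match="share one group"):
            compare_groups_lmm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                               ["low", "high"] * 4,
                               ["t1", "t1", "t2", "t2", "t3", "t3",
                                "t4", "t4"])

    def test_matches_lme4_reference(self, tmp_path):
        """Estimate and LRT p agree with an lme4 ML fit of the same model."""
        scores, groups, tumors = self._planted(seed=7, delta=0.8)
        res = compare_groups_lmm(scores, groups, tumors)
        csv = tmp_path / "lmm.csv"
        pd.DataFrame({"score": scores, "group": groups,
                      "tumor": tumors}).to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$group <- factor(d$group, levels=c("low","high"))
        full <- lmer(score ~ 0 + group + (1|tumor), data=d, REML=FALSE)
        null <- lmer(score ~ 1 + (1|tumor), data=d, REML=FALSE)
        est <- fixef(full)[["grouplow"]] - fixef(full)[["grouphigh"]]
        p <- anova(null, full)[2, "Pr(>Chisq)"]
        cat(sprintf("%.12f %.12g", est, p))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        est_r, p_r = map(float, out.stdout.split())
        assert res.estimate == pytest.approx(est_r, abs=1e-6)
        assert res.p == pytest.approx(p_r, rel=1e-4)


class TestCompareGroupsAll:
    def test_bh_matches_bruteforce_definition(self):
        pws = make_pathways(6)
        cfg = SyntheticConfig(seed=14, n_tumors=6, n_genes=80,
                              cells_per_tumor=(60, 60),
                              planted_pathways=tuple((pw, 0.0)
                                                     for pw in pws))
        cohort, truth = generate_sc_cohort(cfg)
        assignment = assign_infiltration_groups(tcell_fraction(cohort))
        comps = compare_groups_all(cohort, pws, assignment)
        p = np.array([c.p for c in comps])
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        for rank_i, idx in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1)
                          for j in range(rank_i, m)]
            brute[idx] = min(1.0, min(candidates))
        q = np.array([c.q for c in comps])
        assert np.allclose(q, brute, atol=1e-12)
        assert (q >= p - 1e-15).all()
        for c in comps:
            assert c.significant == (c.q < 0.10)

    def test_empty_pathway_list(self):
        cfg = SyntheticConfig(seed=15, n_tumors=4, n_genes=20,
                              cells_per_tumor=(30, 30))
        cohort, _ = generate_sc_cohort(cfg)
        assignment = assign_infiltration_groups(tcell_fraction(cohort))
        assert compare_groups_all(cohort, [], assignment) == []


class TestCompareCelltypesNested:
    def _typed_cohort(self, rng, shift=0.0, n_tumors=4, n_per=30):
        tumors, types, rows = [], [], []
        for t in range(n_tumors):
            bump = rng.normal(0, 0.1)
            for ct in ("malignant", "fibroblast"):
                vals = rng.normal(bump + (shift if ct == "malignant" else 0),
                                  0.3, size=(n_per, 3))
                rows.append(vals)
                tumors += [f"t{t}"] * n_per
                types += [ct] * n_per
        return _cohort(np.vstack(rows), tumors, types)

    def test_null_estimates_centered_and_mostly_nonsignificant(self, rng):
        """Across null draws the estimate centers on 0; small-tumor-count
        LRTs are somewhat liberal, so rejection is bounded, not absent."""
        estimates, rejections = [], 0
        for _ in range(10):
            cohort = self._typed_cohort(rng, shift=0.0)
            scores = cohort.values.mean(axis=1).to_numpy()
            res = compare_celltypes_nested(
                scores, cohort.annotations["cell_type"],
                cohort.annotations["tumor_name"], "malignant", "fibroblast")
            estimates.append(res.estimate)
            rejections += res.p < 0.05
        assert abs(np.mean(estimates)) < 0.1
        assert rejections <= 4

    def test_planted_dominance_recovered(self, rng):
        cohort = self._typed_cohort(rng, shift=2.0, n_tumors=5)
        scores = cohort.values.mean(axis=1).to_numpy()
        res = compare_celltypes_nested(
            scores, cohort.annotations["cell_type"],
            cohort.annotations["tumor_name"], "malignant", "fibroblast")
        assert res.estimate == pytest.approx(2.0, abs=0.4)
        assert res.p < 0.01

    def test_single_tumor_errors(self):
        cohort = _cohort(np.zeros((10, 2)), ["t1"] * 10,
                         ["malignant"] * 5 + ["fibroblast"] * 5)
        with pytest.raises(ValueError, match="<2 tumors"):
            compare_celltypes_nested(
                cohort.values.mean(axis=1).to_numpy(),
                cohort.annotations["cell_type"],
                cohort.annotations["tumor_name"], "malignant", "fibroblast")

    def test_absent_type_errors(self, rng):
        cohort = self._typed_cohort(rng)
        with pytest.raises(ValueError, match="absent"):
            compare_celltypes_nested(
                cohort.values.mean(axis=1).to_numpy(),
                cohort.annotations["cell_type"],
                cohort.annotations["tumor_name"], "malignant", "B cell")


class TestP38Score:
    def test_cohort_mean_is_zero(self, rng):
        sig = builtin_p38_signature()
        vals = rng.normal(5, 1, size=(15, 12))
        expr = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"t{i}" for i in range(15)], columns=sig.genes))
        scores = p38_score_tumors(expr, sig)
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_identical_tumors_error(self):
        sig = builtin_p38_signature()
        expr = ExpressionMatrix(values=pd.DataFrame(
            np.ones((2, 12)), index=["t1", "t2"], columns=sig.genes))
        with pytest.raises(ValueError, match="zero variance"):
            p38_score_tumors(expr, sig)

    def test_zero_variance_gene_dropped(self, rng, caplog):
        sig = GeneSignature("S", ("a", "b"))
        vals = rng.normal(size=(6, 2))
        vals[:, 1] = 3.0
        expr = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"t{i}" for i in range(6)], columns=["a", "b"]))
        scores = p38_score_tumors(expr, sig)
        z = (vals[:, 0] - vals[:, 0].mean()) / vals[:, 0].std(ddof=1)
        assert np.allclose(scores, z, atol=1e-12)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_low_infiltration_shift_detected_by_wilcoxon(self, rng):
        """+1 on the 12 genes in 20 low vs 20 high tumors: one-sided p<0.05."""
        from scipy.stats import mannwhitneyu
        sig = builtin_p38_signature()
        genes = list(sig.genes) + [f"g{i}" for i in range(20)]
        vals = rng.normal(5, 0.5, size=(40, len(genes)))
        vals[:20, :12] += 1.0  # low-infiltration tumors
        expr = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"t{i}" for i in range(40)], columns=genes))
        scores = p38_score_tumors(expr, sig)
        res = mannwhitneyu(scores[:20], scores[20:], alternative="greater")
        assert scores[:20].mean() > scores[20:].mean()
        assert res.pvalue < 0.05

    def test_pseudobulk_is_malignant_mean(self, rng):
        cohort = _cohort(rng.normal(size=(12, 3)),
                         ["A"] * 6 + ["B"] * 6,
                         ["malignant", "T cell"] * 6)
        pb = pseudobulk_malignant(cohort)
        malig = cohort.annotations["is_malignant"]
        expected = cohort.values[malig].groupby(
            cohort.annotations.loc[malig, "tumor_name"]).mean()
        assert np.allclose(pb.values, expected, atol=1e-12)


class TestCellCohortIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        cohort = _cohort(rng.normal(size=(8, 4)), ["A"] * 4 + ["B"] * 4,
                         ["malignant", "T cell"] * 4)
        cohort.to_tsv(tmp_path / "m.tsv", tmp_path / "a.tsv")
        back = CellCohort.from_tsv(tmp_path / "m.tsv", tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(back.values, cohort.values)
        assert (back.annotations["is_malignant"]
                == cohort.annotations["is_malignant"]).all()

    def test_mtx_roundtrip(self, tmp_path, rng):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        cohort = _cohort(rng.poisson(2, size=(6, 5)).astype(float),
                         ["A"] * 3 + ["B"] * 3)
        mmwrite(str(tmp_path / "m.mtx"), csr_matrix(cohort.values.to_numpy().T))
        (tmp_path / "genes.tsv").write_text(
            "\n".join(cohort.values.columns) + "\n")
        (tmp_path / "barcodes.tsv").write_text(
            "\n".join(cohort.values.index) + "\n")
        cohort.annotations.to_csv(tmp_path / "a.tsv", sep="\t")
        back = CellCohort.from_mtx(tmp_path / "m.mtx", tmp_path / "genes.tsv",
                                   tmp_path / "barcodes.tsv",
                                   tmp_path / "a.tsv")
        assert np.allclose(back.values.to_numpy(), cohort.values.to_numpy())

    def test_anndata_roundtrip(self, rng):
        cohort = _cohort(rng.normal(size=(5, 3)), ["A"] * 5)
        back = CellCohort.from_anndata(cohort.to_anndata())
        assert np.allclose(back.values.to_numpy(), cohort.values.to_numpy())
        assert list(back.annotations["tumor_name"]) == ["A"] * 5

    def test_missing_annotation_column_rejected(self, rng):
        values = pd.DataFrame(rng.normal(size=(2, 2)), index=["c1", "c2"],
                              columns=["g1", "g2"])
        ann = pd.DataFrame({"tumor_name": ["A", "A"]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="cell_type"):
            CellCohort(values=values, annotations=ann)
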