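"""Moderated contrasts, DEG selection, the configuration grid and the
intersection rule."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from dermprof import (
    StudyConfig,
    apply_batch_adjustment,
    fit_moderated_contrasts,
    generate_study,
    intersect_configurations,
    select_degs,
    summarize_degs,
)
from dermprof.degsel import (
    ContrastTable,
    ModerationParams,
    estimate_variance_prior,
    run_configuration_grid,
)


def _simulate_expression(n_genes=50, n_per=(6, 8), effects=None, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(
        [f"C{i}" for i, n in enumerate(n_per) for _ in range(n)], dtype=object
    )
    mu = rng.normal(8, 1, size=n_genes)
    x = mu[:, None] + rng.normal(0, 0.6, size=(n_genes, len(labels)))
    if effects is not None:
        for g, cls, e in effects:
            x[g, labels == cls] += e
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return pd.DataFrame(x, index=genes, columns=[f"s{j}" for j in range(len(labels))]), labels


def brute_force_moderated(x: np.ndarray, labels: np.ndarray):
    """Independent moderated-t oracle: explicit loops, moment equation
    solved by log-spaced scan plus bisection, t from first principles."""
    classes = sorted(set(labels))
    n, k = x.shape[1], len(classes)
    d_g = n - k
    s2 = np.empty(x.shape[0])
    means = {}
    for gi in range(x.shape[0]):
        sse = 0.0
        for c in classes:
            vals = x[gi, labels == c]
            means[(gi, c)] = vals.mean()
            sse += ((vals - vals.mean()) ** 2).sum()
        s2[gi] = max(sse / d_g, 1e-12)
    g = len(s2)
    e = np.log(s2) - special.digamma(d_g / 2) + np.log(d_g / 2)
    target = np.mean((e - e.mean()) ** 2) * g / (g - 1) - special.polygamma(1, d_g / 2)
    if target <= 0:
        d0, s0 = np.inf, float(np.mean(s2))
    else:
        grid = np.logspace(-6, 6, 4001)
        vals = special.polygamma(1, grid) - target
        idx = int(np.argmax(vals < 0))  # trigamma decreasing
        lo, hi = grid[idx - 1], grid[idx]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if special.polygamma(1, mid) - target > 0:
                lo = mid
            else:
                hi = mid
        y = 0.5 * (lo + hi)
        d0 = 2 * y
        s0 = float(np.exp(e.mean() + special.digamma(y) - np.log(y)))
    out = {}
    for a, b in itertools.combinations(classes, 2):
        na = int((labels == a).sum())
        nb = int((labels == b).sum())
        for gi in range(x.shape[0]):
            if np.isinf(d0):
                s2post = s0
            else:
                s2post = (d0 * s0 + d_g * s2[gi]) / (d0 + d_g)
            df = min(d0 + d_g, x.shape[0] * d_g)  # pooled-df cap
            lfc = means[(gi, a)] - means[(gi, b)]
            t = lfc / np.sqrt(s2post * (1 / na + 1 / nb))
            p = 2 * stats.t.sf(abs(t), df)
            out[(gi, f"{a}-{b}")] = (lfc, t, p)
    return d0, s0, out


class TestModeratedContrasts:
    def test_seven_classes_give_21_contrasts(self):
        expr, labels = _simulate_expression(n_genes=5, n_per=(3,) * 7)
        table = fit_moderated_contrasts(expr, labels, compute_b=False)
        assert len(table.contrasts) == 21
        assert table.lfc.shape == (5, 21)

    def test_identical_residual_variances_collapse_to_ordinary_t(self):
        """When every gene has exactly the same residual variance the moment
        equation returns an infinite prior df and the moderated t equals the
        ordinary pooled-variance t."""
        n_genes, c = 20, 0.7
        rng = np.random.default_rng(0)
        mu = rng.normal(8, 1, n_genes)
        delta = rng.normal(0, 2, n_genes)
        rows = []
        for g in range(n_genes):
            rows.append(
                np.concatenate([mu[g] + c * np.array([-1, 0, 1]),
                                mu[g] + delta[g] + c * np.array([-1, 0, 1])])
            )
        expr = pd.DataFrame(rows, columns=[f"s{j}" for j in range(6)])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        table = fit_moderated_contrasts(expr, labels, compute_b=False)
        assert np.isinf(table.moderation.d0)
        s2 = c**2 * 2 * 2 / 4  # sse/(n-k)
        assert table.moderation.s0_2 == pytest.approx(s2)
        expected_t = -delta / np.sqrt(s2 * (2 / 3))  # contrast is A - B
        assert np.allclose(table.t.iloc[:, 0].to_numpy(), expected_t)

    def test_matches_brute_force_oracle(self):
        expr, labels = _simulate_expression(
            n_genes=50, n_per=(6, 8), effects=[(0, "C0", 3.0), (5, "C1", -2.0)], seed=3
        )
        table = fit_moderated_contrasts(expr, labels, compute_b=False)
        d0, s0, oracle = brute_force_moderated(expr.to_numpy(), labels)
        assert table.moderation.d0 == pytest.approx(d0, rel=1e-6)
        assert table.moderation.s0_2 == pytest.approx(s0, rel=1e-6)
        for (gi, contrast), (lfc, t, p) in oracle.items():
            gene = expr.index[gi]
            assert table.lfc.loc[gene, contrast] == pytest.approx(lfc, abs=1e-10)
            assert table.t.loc[gene, contrast] == pytest.approx(t, rel=1e-8)
            assert table.p.loc[gene, contrast] == pytest.approx(p, rel=1e-6, abs=1e-300)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check the whole moderated-t path against the reference
        empirical-Bayes implementation in R."""
        expr, labels = _simulate_expression(
            n_genes=80, n_per=(5, 6, 7), effects=[(0, "C0", 4.0)], seed=7
        )
        expr.to_csv(tmp_path / "x.tsv", sep="\t")
        (tmp_path / "labels.txt").write_text("\n".join(labels) + "\n")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))
            cls <- scan(args[2], what="character", quiet=TRUE)
            f <- factor(cls)
            design <- model.matrix(~0+f)
            colnames(design) <- levels(f)
            cm <- cbind("C0-C1"=c(1,-1,0), "C0-C2"=c(1,0,-1), "C1-C2"=c(0,1,-1))
            fit <- eBayes(contrasts.fit(lmFit(x, design), cm))
            out <- data.frame(gene=rownames(x),
                              lfc1=fit$coefficients[,1], t1=fit$t[,1], p1=fit$p.value[,1],
                              lfc2=fit$coefficients[,2], t2=fit$t[,2], p2=fit$p.value[,2])
            out$d0 <- fit$df.prior
            out$s02 <- fit$s2.prior
            write.table(out, args[3], sep="\t", row.names=FALSE, quote=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "x.tsv"),
             str(tmp_path / "labels.txt"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        table = fit_moderated_contrasts(expr, labels, compute_b=False)
        assert table.moderation.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
        assert table.moderation.s0_2 == pytest.approx(ref["s02"].iloc[0], rel=1e-3)
        assert np.allclose(table.lfc["C0-C1"], ref["lfc1"], atol=1e-8)
        assert np.allclose(table.t["C0-C1"], ref["t1"], rtol=1e-4)
        assert np.allclose(table.p["C0-C1"], ref["p1"], rtol=1e-3)
        assert np.allclose(table.t["C0-C2"], ref["t2"], rtol=1e-4)

    def test_hyperparameter_recovery(self):
        d0_true, s0_true, d_g, g = 4.0, 2.0, 10.0, 5000
        rng = np.random.default_rng(2024)
        s2 = s0_true * stats.f.rvs(d_g, d0_true, size=g, random_state=rng)
        d0_hat, s0_hat = estimate_variance_prior(s2, d_g)
        assert abs(d0_hat - d0_true) / d0_true < 0.15
        assert abs(s0_hat - s0_true) / s0_true < 0.10

    def test_antisymmetry_under_relabeling(self):
        expr, labels = _simulate_expression(n_genes=10, n_per=(5, 5), seed=4)
        fwd = fit_moderated_contrasts(expr, labels, compute_b=False)
        flipped = np.where(labels == "C0", "Z0", "A1")  # reverses sort order
        rev = fit_moderated_contrasts(expr, flipped, compute_b=False)
        assert np.allclose(fwd.lfc["C0-C1"], -rev.lfc["A1-Z0"])
        assert np.allclose(fwd.t["C0-C1"], -rev.t["A1-Z0"])
        assert np.allclose(fwd.p["C0-C1"], rev.p["A1-Z0"])

    def test_moderation_bracketing_and_adjusted_p(self):
        expr, labels = _simulate_expression(n_genes=40, n_per=(5, 6), seed=5)
        table = fit_moderated_contrasts(expr, labels, compute_b=False)
        s2 = table.moderation.s2.to_numpy()
        post = table.moderation.s2_post.to_numpy()
        lo = np.minimum(s2, table.moderation.s0_2)
        hi = np.maximum(s2, table.moderation.s0_2)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()
        assert (table.p_adj.to_numpy() >= table.p.to_numpy() - 1e-15).all()

    def test_tiny_class_dropped_with_warning(self):
        expr, labels = _simulate_expression(n_genes=5, n_per=(5, 5, 1), seed=6)
        with pytest.warns(UserWarning, match="C2"):
            table = fit_moderated_contrasts(expr, labels, compute_b=False)
        assert len(table.contrasts) == 1


def _toy_table(lfc_by_contrast: dict[str, float], p_by_contrast: dict[str, float]):
    contrasts = [tuple(c.split("-")) for c in lfc_by_contrast]
    lfc = pd.DataFrame([list(lfc_by_contrast.values())], index=["gene1"],
                       columns=list(lfc_by_contrast))
    p = pd.DataFrame([list(p_by_contrast.values())], index=["gene1"],
                     columns=list(p_by_contrast))
    mod = ModerationParams(
        d0=4.0, s0_2=1.0, s2=pd.Series([1.0], index=["gene1"]),
        df_residual=10.0, s2_post=pd.Series([1.0], index=["gene1"]),
    )
    return ContrastTable(
        contrasts=contrasts, lfc=lfc, t=lfc * 3, p=p, p_adj=p, b=lfc * 10,
        moderation=mod,
    )


class TestSelection:
    def test_threshold_pass_counts_cases(self):
        table = _toy_table({"A-B": 4.5, "A-C": 2.0}, {"A-B": 1e-5, "A-C": 1e-9})
        degs, counts = select_degs(table)
        assert degs == {"gene1"}
        assert counts["gene1"] == 1

    def test_lfc_failure_dominates_tiny_p(self):
        table = _toy_table({"A-B": 3.9}, {"A-B": 1e-20})
        degs, _ = select_degs(table)
        assert degs == set()

    @pytest.mark.parametrize("lfc2,p2", [(5.0, 0.01), (4.5, 1e-5)])
    def test_selection_monotone_in_thresholds(self, lfc2, p2):
        table = _toy_table({"A-B": 4.2, "A-C": lfc2}, {"A-B": 5e-4, "A-C": p2})
        base, _ = select_degs(table, lfc_min=4.0, p_max=0.001)
        stricter_lfc, _ = select_degs(table, lfc_min=4.6, p_max=0.001)
        stricter_p, _ = select_degs(table, lfc_min=4.0, p_max=1e-6)
        assert stricter_lfc <= base and stricter_p <= base

    def test_nordi_discretized_values_cannot_pass_lfc4(self, merged_mean):
        adjusted = apply_batch_adjustment(merged_mean, "NORDI")
        table = fit_moderated_contrasts(
            adjusted.expression, adjusted.class_labels(), compute_b=False
        )
        assert table.lfc.abs().to_numpy().max() <= 2.0
        degs, _ = select_degs(table)
        assert degs == set()


class TestIntersection:
    def test_plain_intersection(self):
        inter, contrib, status = intersect_configurations(
            {"c1": {"A", "B"}, "c2": {"B", "C"}}
        )
        assert inter == {"B"} and status == "ok"
        assert contrib == ["c1", "c2"]

    def test_empty_configurations_excluded(self):
        inter, contrib, _ = intersect_configurations(
            {"c1": {"A", "B"}, "c2": set(), "c3": {"B"}}
        )
        assert inter == {"B"}
        assert contrib == ["c1", "c3"]

    def test_all_empty_reports_status(self):
        inter, contrib, status = intersect_configurations({"c1": set(), "c2": set()})
        assert inter == set() and contrib == [] and status == "all_configurations_empty"


class TestGrid:
    def test_twelve_cells_and_determinism(self, small_bundles):
        grid1 = run_configuration_grid(small_bundles, keep_tables=False)
        grid2 = run_configuration_grid(small_bundles, keep_tables=False)
        assert len(grid1.cells) == 12
        assert grid1.count_table().shape == (6, 2)
        assert grid1.deg_sets() == grid2.deg_sets()
        assert all(c.error is None for c in grid1.cells.values())

    def test_intersection_contained_in_every_contributor(self, small_bundles):
        grid = run_configuration_grid(small_bundles, keep_tables=False)
        inter, contrib, _ = intersect_configurations(grid.deg_sets())
        for name in contrib:
            assert inter <= grid.deg_sets()[name]


class TestSummary:
    def test_two_contrast_mean_and_sample_sd(self):
        table = _toy_table({"A-B": 4.0, "A-C": 6.0, "B-C": 1.0},
                           {"A-B": 1e-6, "A-C": 1e-8, "B-C": 0.5})
        out = summarize_degs(table, ["gene1"])
        assert out.loc[0, "deg_cases"] == 2
        assert out.loc[0, "mu_lfc"] == pytest.approx(5.0)
        assert out.loc[0, "sd_lfc"] == pytest.approx(np.sqrt(2.0))
        assert out.loc[0, "pv_min"] == 1e-8 and out.loc[0, "pv_max"] == 1e-6

    def test_single_case_sd_zero(self):
        table = _toy_table({"A-B": 4.4}, {"A-B": 1e-9})
        out = summarize_degs(table, ["gene1"])
        assert out.loc[0, "sd_lfc"] == 0.0 and out.loc[0, "sd_t"] == 0.0

    def test_rows_ordered_by_mean_absolute_lfc(self, small_bundles, small_truth):
        grid = run_configuration_grid(small_bundles, unions=("mean",), methods=("MRS",))
        cell = grid.cells[("MRS", "mean")]
        out = summarize_degs(cell.table, sorted(cell.deg_set))
        assert (out["mu_lfc"].diff().dropna() <= 1e-12).all()
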