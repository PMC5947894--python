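"""Moderated differential expression over pairwise class contrasts.

Per gene, a one-way layout across the observed classes gives group means
and a residual variance s_g^2 on d_g = n - K degrees of freedom.  The
variances are shrunk toward a common prior by empirical Bayes: with
e_g = log s_g^2 - psi(d_g/2) + log(d_g/2), the prior degrees of freedom d0
solve psi'(d0/2) = Var(e) - mean psi'(d_g/2) (d0 = infinity when the
right-hand side is non-positive) and the prior variance is
s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2)).  The posterior variance

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

replaces s_g^2 in the t statistic of every pairwise contrast, which then
has d0 + d_g degrees of freedom.  A gene is a DEG when some contrast passes
|LFC| >= 4 and p <= 0.001; with 7 classes there are 21 contrasts and the
per-gene "DEG cases" count is the number of passing contrasts.

The configuration grid runs the identical selection under 6 batch methods x
2 probe-union methods; the final list is the intersection of the DEG sets
of the configurations that returned candidates at all.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from dermprof.batchfx import BATCH_METHODS, apply_batch_adjustment
from dermprof.integrate import MergedSet, summarize_and_merge

_S2_FLOOR = 1e-12


def estimate_variance_prior(
    s2: np.ndarray, df: np.ndarray | float
) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching on log variances; returns ``d0 = inf`` (and the plain
    mean of ``s2`` as ``s0^2``) when the observed spread of log variances
    is no larger than expected from the residual degrees of freedom alone.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _S2_FLOOR)
    g = s2.size
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    if g < 2:
        return np.inf, float(s2.mean())
    target = np.mean((e - e_bar) ** 2 * g / (g - 1.0) - special.polygamma(1, df / 2.0))
    if target <= 0:
        return np.inf, float(s2.mean())
    # psi'(y) is monotone decreasing; solve psi'(d0/2) = target
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, hi) > target:
        return np.inf, float(s2.mean())
    y = brentq(lambda v: special.polygamma(1, v) - target, lo, hi, xtol=1e-12)
    d0 = 2.0 * y
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


@dataclass
class ModerationParams:
    d0: float
    s0_2: float
    s2: pd.Series  # per-gene residual variance
    df_residual: float
    s2_post: pd.Series


@dataclass
class ContrastTable:
    """Per-gene, per-contrast moderated statistics."""

    contrasts: list[tuple[str, str]]
    lfc: pd.DataFrame  # genes x contrasts, log2 units
    t: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame  # Benjamini-Hochberg within each contrast
    b: pd.DataFrame | None
    moderation: ModerationParams

    @staticmethod
    def contrast_name(a: str, b: str) -> str:
        return f"{a}-{b}"

    @property
    def genes(self) -> list[str]:
        return list(self.lfc.index)


class ModeratedContrasts(BaseEstimator):
    """Estimator fitting moderated t statistics for all pairwise contrasts.

    sklearn-style: ``fit(X, y)`` with ``X`` of shape (n_samples, n_genes)
    and ``y`` the class labels; fitted attributes carry the contrast table.
    """

    def __init__(self, compute_b: bool = True, de_proportion: float = 0.01):
        self.compute_b = compute_b
        self.de_proportion = de_proportion

    def fit(self, X, y, gene_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_genes) matching y")
        if not np.all(np.isfinite(X)):
            raise ValueError("expression contains missing or non-finite values")
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
        genes = list(gene_names)

        labels, counts = np.unique(y, return_counts=True)
        usable = [l for l, c in zip(labels, counts) if c >= 2]
        dropped = [str(l) for l, c in zip(labels, counts) if c < 2]
        if dropped:
            warnings.warn(
                f"classes with < 2 samples dropped from contrasts: {dropped}"
            )
        if len(usable) < 2:
            raise ValueError("need >= 2 classes with >= 2 samples each")

        n = sum(int(counts[list(labels).index(l)]) for l in usable)
        k = len(usable)
        means = {}
        sse = np.zeros(X.shape[1])
        n_per = {}
        for l in usable:
            sub = X[y == l]
            n_per[l] = sub.shape[0]
            means[l] = sub.mean(axis=0)
            sse += ((sub - means[l]) ** 2).sum(axis=0)
        d_g = float(n - k)
        s2 = np.maximum(sse / d_g, _S2_FLOOR)

        d0, s0_2 = estimate_variance_prior(s2, d_g)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        else:
            s2_post = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
        # p-values use the posterior df, capped at the pooled residual df
        # across genes (the conventional finite-sample cap when d0 = inf)
        df_total = min(d0 + d_g, len(genes) * d_g)

        contrasts = list(itertools.combinations(sorted(map(str, usable)), 2))
        cols = [ContrastTable.contrast_name(a, b) for a, b in contrasts]
        lfc = np.empty((X.shape[1], len(contrasts)))
        tstat = np.empty_like(lfc)
        unscaled2 = np.empty(len(contrasts))
        for j, (a, b) in enumerate(contrasts):
            la = [l for l in usable if str(l) == a][0]
            lb = [l for l in usable if str(l) == b][0]
            diff = means[la] - means[lb]
            u2 = 1.0 / n_per[la] + 1.0 / n_per[lb]
            unscaled2[j] = u2
            lfc[:, j] = diff
            tstat[:, j] = diff / np.sqrt(s2_post * u2)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)

        p_adj = np.empty_like(pvals)
        for j in range(pvals.shape[1]):
            p_adj[:, j] = multipletests(pvals[:, j], method="fdr_bh")[1]

        b_mat = None
        if self.compute_b:
            b_mat = self._lods(tstat, unscaled2, df_total)

        self.classes_ = [str(l) for l in usable]
        self.n_per_class_ = {str(l): n_per[l] for l in usable}
        self.moderation_ = ModerationParams(
            d0=d0,
            s0_2=s0_2,
            s2=pd.Series(s2, index=genes),
            df_residual=d_g,
            s2_post=pd.Series(s2_post, index=genes),
        )
        self.contrast_table_ = ContrastTable(
            contrasts=contrasts,
            lfc=pd.DataFrame(lfc, index=genes, columns=cols),
            t=pd.DataFrame(tstat, index=genes, columns=cols),
            p=pd.DataFrame(pvals, index=genes, columns=cols),
            p_adj=pd.DataFrame(p_adj, index=genes, columns=cols),
            b=None if b_mat is None else pd.DataFrame(b_mat, index=genes, columns=cols),
            moderation=self.moderation_,
        )
        return self

    def _lods(
        self, tstat: np.ndarray, unscaled2: np.ndarray, df_total: float
    ) -> np.ndarray:
        """Log posterior odds of differential expression.

        The DE-component variance v0 is matched so that the theoretical
        upper tail of the moderated t reaches the observed upper 1% of |t|.
        """
        p1 = self.de_proportion
        b = np.empty_like(tstat)
        for j in range(tstat.shape[1]):
            t = tstat[:, j]
            t99 = np.quantile(np.abs(t), 0.99)
            if np.isinf(df_total):
                t_theor = stats.norm.ppf(1 - 0.005)
            else:
                t_theor = stats.t.ppf(1 - 0.005, df_total)
            v0_ratio = max(0.0, (t99 / t_theor) ** 2 - 1.0)
            r = 1.0 + v0_ratio  # (u^2 + v0) / u^2
            t2 = t * t
            if np.isinf(df_total):
                kernel = t2 * (1.0 - 1.0 / r) / 2.0
            else:
                kernel = (
                    (df_total + 1.0)
                    / 2.0
                    * np.log((t2 + df_total) / (t2 / r + df_total))
                )
            b[:, j] = np.log(p1 / (1.0 - p1)) - 0.5 * np.log(r) + kernel
        return b


def fit_moderated_contrasts(
    expression: pd.DataFrame, classes: Sequence[str], compute_b: bool = True
) -> ContrastTable:
    """Fit moderated t statistics on a genes x samples matrix."""
    est = ModeratedContrasts(compute_b=compute_b)
    est.fit(
        expression.to_numpy().T,
        np.asarray(list(classes)),
        gene_names=list(expression.index),
    )
    return est.contrast_table_


# ---------------------------------------------------------------------------
# selection, grid and intersection


def select_degs(
    table: ContrastTable,
    lfc_min: float = 4.0,
    p_max: float = 0.001,
    p_type: str = "raw",
) -> tuple[set[str], pd.Series]:
    """Select DEGs: some contrast with |LFC| >= lfc_min and p <= p_max.

    Returns the DEG set and the per-gene count of passing contrasts
    ("DEG cases").  ``p_type`` chooses raw or Benjamini-Hochberg adjusted p.
    """
    if lfc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    if p_type not in ("raw", "adjusted"):
        raise ValueError("p_type must be 'raw' or 'adjusted'")
    p = table.p if p_type == "raw" else table.p_adj
    passing = (table.lfc.abs() >= lfc_min) & (p <= p_max)
    case_counts = passing.sum(axis=1)
    degs = set(case_counts.index[case_counts > 0])
    return degs, case_counts


@dataclass
class GridCell:
    batch_method: str
    union_method: str
    deg_set: set[str] = field(default_factory=set)
    case_counts: pd.Series | None = None
    table: ContrastTable | None = None
    merged: MergedSet | None = None
    error: str | None = None

    @property
    def n_degs(self) -> int:
        return len(self.deg_set)


@dataclass
class GridResult:
    cells: dict[tuple[str, str], GridCell]

    def count_table(self) -> pd.DataFrame:
        """Batch-method x union-method table of DEG counts."""
        methods = sorted({m for m, _ in self.cells})
        unions = sorted({u for _, u in self.cells})
        data = {
            u: [
                self.cells[(m, u)].n_degs if self.cells[(m, u)].error is None else np.nan
                for m in methods
            ]
            for u in unions
        }
        return pd.DataFrame(data, index=methods)

    def deg_sets(self) -> dict[str, set[str]]:
        return {
            f"{m}/{u}": cell.deg_set
            for (m, u), cell in self.cells.items()
            if cell.error is None
        }


def run_configuration_grid(
    bundles,
    methods: Sequence[str] = BATCH_METHODS,
    unions: Sequence[str] = ("mean", "median"),
    lfc_min: float = 4.0,
    p_max: float = 0.001,
    p_type: str = "raw",
    batch_params: Mapping[str, Mapping] | None = None,
    keep_tables: bool = True,
) -> GridResult:
    """Run the (batch method x union method) configuration grid.

    Each configuration executes the identical pipeline — probe union, merge,
    batch adjustment, moderated contrasts, thresholding — varying only the
    two factors.  A failing configuration is recorded in its cell and the
    grid continues.
    """
    batch_params = dict(batch_params or {})
    cells: dict[tuple[str, str], GridCell] = {}
    for union in unions:
        merged = summarize_and_merge(bundles, union_method=union)
        for method in methods:
            cell = GridCell(batch_method=method, union_method=union)
            try:
                adjusted = apply_batch_adjustment(
                    merged, method, **batch_params.get(method, {})
                )
                table = fit_moderated_contrasts(
                    adjusted.expression, adjusted.class_labels(), compute_b=True
                )
                degs, counts = select_degs(table, lfc_min, p_max, p_type)
                cell.deg_set = degs
                cell.case_counts = counts
                if keep_tables:
                    cell.table = table
                    cell.merged = adjusted
            except Exception as exc:  # record and continue
                cell.error = f"{type(exc).__name__}: {exc}"
            cells[(method, union)] = cell
    return GridResult(cells=cells)


def intersect_configurations(
    deg_sets: Mapping[str, set[str]]
) -> tuple[set[str], list[str], str]:
    """Intersect the DEG sets of configurations that returned candidates.

    Configurations with empty sets "return no candidates" and are excluded
    from the intersection.  Returns (intersection, contributing
    configuration names, status).
    """
    if not deg_sets:
        raise ValueError("need at least one configuration")
    contributing = sorted(name for name, s in deg_sets.items() if s)
    if not contributing:
        return set(), [], "all_configurations_empty"
    inter = set.intersection(*(set(deg_sets[name]) for name in contributing))
    return inter, contributing, "ok"


@dataclass
class DEGSelection:
    """Final DEG selection across the configuration grid."""

    per_config_sets: dict[str, set[str]]
    intersection: set[str]
    contributing: list[str]
    status: str
    case_counts: pd.Series | None = None
    summary: pd.DataFrame | None = None


def summarize_degs(
    table: ContrastTable,
    deg_genes: Sequence[str],
    lfc_min: float = 4.0,
    p_max: float = 0.001,
    p_type: str = "raw",
    sd_convention: str = "sample",
) -> pd.DataFrame:
    """Per-gene summary over significant contrasts, ordered by |mu_LFC|.

    For each gene: the number of DEG cases, mean +/- SD of |LFC|, |t| and
    |B| over its passing contrasts, and the [min, max] range of p.  SD uses
    the sample convention (ddof=1, zero for a single case) unless
    ``sd_convention='population'``.
    """
    if sd_convention not in ("sample", "population"):
        raise ValueError("sd_convention must be 'sample' or 'population'")
    ddof = 1 if sd_convention == "sample" else 0
    p = table.p if p_type == "raw" else table.p_adj
    rows = []
    for gene in deg_genes:
        passing = (table.lfc.loc[gene].abs() >= lfc_min) & (p.loc[gene] <= p_max)
        cols = passing.index[passing]
        if len(cols) == 0:
            continue
        lfc = table.lfc.loc[gene, cols].abs()
        t = table.t.loc[gene, cols].abs()
        pv = p.loc[gene, cols]

        def _sd(v: pd.Series) -> float:
            return 0.0 if len(v) < 2 else float(v.std(ddof=ddof))

        row = {
            "gene_symbol": gene,
            "deg_cases": int(len(cols)),
            "mu_lfc": float(lfc.mean()),
            "sd_lfc": _sd(lfc),
            "mu_t": float(t.mean()),
            "sd_t": _sd(t),
            "pv_min": float(pv.min()),
            "pv_max": float(pv.max()),
        }
        if table.b is not None:
            bvals = table.b.loc[gene, cols].abs()
            row["mu_b"] = float(bvals.mean())
            row["sd_b"] = _sd(bvals)
        rows.append(row)
    if not rows:
        raise ValueError("no gene has a significant contrast to summarize")
    out = pd.DataFrame(rows).sort_values("mu_lfc", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def select_final_degs(
    grid: GridResult,
    reference: tuple[str, str] = ("MRS", "mean"),
    lfc_min: float = 4.0,
    p_max: float = 0.001,
    p_type: str = "raw",
) -> DEGSelection:
    """Intersect the grid's non-empty DEG sets and summarize on a reference
    configuration (default: MRS batch adjustment with mean union)."""
    sets = grid.deg_sets()
    inter, contributing, status = intersect_configurations(sets)
    case_counts = None
    summary = None
    ref_cell = grid.cells.get(reference)
    if inter and ref_cell is not None and ref_cell.table is not None:
        case_counts = ref_cell.case_counts.loc[sorted(inter)]
        summary = summarize_degs(ref_cell.table, sorted(inter), lfc_min, p_max, p_type)
    return DEGSelection(
        per_config_sets=sets,
        intersection=inter,
        contributing=contributing,
        status=status,
        case_counts=case_counts,
        summary=summary,
    )
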