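"""Robustness assessment of the final DEG set.

Two tools: a least-squares deviation variable analysed by multi-factor
ANOVA, and Ward hierarchical clustering of class-representative samples.

The LS-deviation variable condenses all candidate genes into one response:
with ``x_bar_g`` the mean of gene g over every sample and every surviving
preprocessing configuration, the observation for (sample s, configuration
c) is the mean over genes of ``(x_gsc - x_bar_g)^2`` (log2^2 units).  Each
observation carries the factors TYPE (skin state), BATCH (batch-adjustment
method), METHOD (probe-union method) and COUNTRY, and a main-effects ANOVA
with sum-to-zero coding and Type III sums of squares asks which factors
drive the deviation.  A robust gene set shows a strong TYPE effect and a
negligible METHOD effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from dermprof.synthio import SampleAnnotation

FACTORS = ("TYPE", "BATCH", "METHOD", "COUNTRY")


def ls_deviation_table(
    variants: Sequence[tuple[str, str, pd.DataFrame]],
    annotations: Sequence[SampleAnnotation],
) -> pd.DataFrame:
    """Build the LS-deviation observations.

    ``variants`` is a list of ``(batch_method, union_method, matrix)`` with
    every matrix a genes x samples table restricted to the candidate genes;
    all variants must share gene list and samples.  Returns one row per
    (sample, variant) with columns ``value``, TYPE, BATCH, METHOD, COUNTRY,
    ``sample_id`` and ``configuration``.
    """
    if not variants:
        raise ValueError("need at least one variant")
    genes = list(variants[0][2].index)
    samples = list(variants[0][2].columns)
    for bm, um, mat in variants:
        if list(mat.index) != genes or list(mat.columns) != samples:
            raise ValueError(
                f"variant {bm}/{um} does not share gene list and samples "
                "with the first variant"
            )
    ann = {a.sample_id: a for a in annotations}
    missing = [s for s in samples if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")

    stack = np.stack([mat.to_numpy() for _, _, mat in variants])  # v x g x s
    grand = stack.mean(axis=(0, 2), keepdims=True)  # per-gene mean
    dev = ((stack - grand) ** 2).mean(axis=1)  # v x s

    rows = []
    for vi, (bm, um, _) in enumerate(variants):
        for si, sid in enumerate(samples):
            a = ann[sid]
            rows.append(
                {
                    "value": float(dev[vi, si]),
                    "TYPE": a.class_label,
                    "BATCH": bm,
                    "METHOD": um,
                    "COUNTRY": a.country,
                    "sample_id": sid,
                    "configuration": f"{bm}/{um}",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Main-effects ANOVA table: per-factor SS/df/MS/F/p plus residual and
    total corrected rows."""

    table: pd.DataFrame  # index: factors + RESIDUAL + TOTAL (CORRECTED)

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "source"
        out.to_csv(path, sep="\t", float_format="%.6g")


def _check_aliasing(data: pd.DataFrame, factors: Sequence[str]) -> None:
    for i, a in enumerate(factors):
        for b in factors[i + 1 :]:
            tab = pd.crosstab(data[a], data[b])
            a_to_b = (tab > 0).sum(axis=1)
            b_to_a = (tab > 0).sum(axis=0)
            if (a_to_b == 1).all() and (b_to_a == 1).all():
                raise ValueError(
                    f"factors {a!r} and {b!r} are aliased "
                    "(their level partitions coincide)"
                )


def anova_main_effects(
    observations: pd.DataFrame,
    factors: Sequence[str] = FACTORS,
    response: str = "value",
) -> AnovaResult:
    """Main-effects ANOVA with sum-to-zero coding and Type III SS.

    Factors with a single observed level are rejected; fully aliased factor
    pairs raise naming the pair.  F ratios test each factor's partial SS
    against the residual mean square.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = observations.copy()
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"missing factor column {f!r}")
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    _check_aliasing(data, factors)

    n = len(data)
    model_df = sum(data[f].nunique() - 1 for f in factors)
    if n <= model_df + 1:
        raise ValueError("not enough observations for the requested factors")

    terms = " + ".join(f"C({f}, Sum)" for f in factors)
    fit = smf.ols(f"{response} ~ {terms}", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(fit, typ=3)

    rows = {}
    for f in factors:
        key = f"C({f}, Sum)"
        ss = float(aov.loc[key, "sum_sq"])
        df = float(aov.loc[key, "df"])
        ms = ss / df
        rows[f] = {"sum_sq": ss, "df": df, "mean_sq": ms}
    ss_res = float(aov.loc["Residual", "sum_sq"])
    df_res = float(aov.loc["Residual", "df"])
    ms_res = ss_res / df_res
    y = data[response].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())

    for f in factors:
        rows[f]["F"] = rows[f]["mean_sq"] / ms_res
        rows[f]["p"] = float(stats.f.sf(rows[f]["F"], rows[f]["df"], df_res))
    table = pd.DataFrame(rows).T
    table.loc["RESIDUAL"] = {
        "sum_sq": ss_res,
        "df": df_res,
        "mean_sq": ms_res,
        "F": np.nan,
        "p": np.nan,
    }
    table.loc["TOTAL (CORRECTED)"] = {
        "sum_sq": ss_total,
        "df": float(n - 1),
        "mean_sq": np.nan,
        "F": np.nan,
        "p": np.nan,
    }
    return AnovaResult(table=table)


# ---------------------------------------------------------------------------
# Ward clustering of representative samples


@dataclass
class WardClustering:
    sample_ids: list[str]  # clustered samples, input order
    linkage_: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]  # tighter-subtree-first traversal
    representatives: dict[str, list[str]]  # class -> chosen sample ids

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_[:, 2]

    def to_newick(self) -> str:
        n = len(self.sample_ids)

        def render(node: int) -> str:
            if node < n:
                return self.sample_ids[node]
            row = self.linkage_[node - n]
            a, b = int(row[0]), int(row[1])
            a, b = _order_children(self.linkage_, n, a, b)
            return f"({render(a)},{render(b)}):{row[2]:.6g}"

        return render(2 * n - 2) + ";"


def _subtree_height(linkage_matrix: np.ndarray, n: int, node: int) -> float:
    return 0.0 if node < n else float(linkage_matrix[node - n, 2])


def _order_children(linkage_matrix, n, a, b):
    ha, hb = _subtree_height(linkage_matrix, n, a), _subtree_height(linkage_matrix, n, b)
    if (hb, b) < (ha, a):  # tighter (lower) subtree first; ties by index
        return b, a
    return a, b


def _leaf_traversal(linkage_matrix: np.ndarray, n: int) -> list[int]:
    order: list[int] = []

    def walk(node: int) -> None:
        if node < n:
            order.append(node)
            return
        row = linkage_matrix[node - n]
        a, b = _order_children(linkage_matrix, n, int(row[0]), int(row[1]))
        walk(a)
        walk(b)

    walk(2 * n - 2)
    return order


def pick_representatives(
    expression: pd.DataFrame,
    classes: Mapping[str, str],
    samples_per_class: int = 5,
) -> dict[str, list[str]]:
    """Per class, the ``samples_per_class`` samples nearest to the class
    centroid in Euclidean distance over the selected genes."""
    by_class: dict[str, list[str]] = {}
    for sid, cls in classes.items():
        by_class.setdefault(cls, []).append(sid)
    reps: dict[str, list[str]] = {}
    for cls, sids in sorted(by_class.items()):
        sub = expression[sids].to_numpy()
        centroid = sub.mean(axis=1, keepdims=True)
        dist = np.sqrt(((sub - centroid) ** 2).sum(axis=0))
        if len(sids) < samples_per_class:
            warnings.warn(
                f"class {cls} has only {len(sids)} samples "
                f"(< {samples_per_class}); taking all"
            )
        order = np.argsort(dist, kind="stable")[:samples_per_class]
        reps[cls] = [sids[i] for i in sorted(order)]
    return reps


def ward_cluster(
    expression: pd.DataFrame,
    classes: Mapping[str, str] | Sequence[str],
    samples_per_class: int = 5,
) -> WardClustering:
    """Ward minimum-variance clustering of class-representative samples.

    ``expression`` is genes x samples restricted to the gene set of
    interest; ``classes`` maps sample id to class (or lists classes in
    column order).  Leaves are ordered by a recursive traversal placing the
    tighter (lower-linkage) subtree first.
    """
    if not isinstance(classes, Mapping):
        classes = dict(zip(expression.columns, classes))
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (expression.std(axis=1) == 0).all():
        raise ValueError("all selected genes are constant")

    reps = pick_representatives(expression, classes, samples_per_class)
    chosen = [sid for cls in sorted(reps) for sid in reps[cls]]
    sub = expression[chosen].to_numpy().T  # samples x genes
    z = linkage(pdist(sub, metric="euclidean"), method="ward")
    order = _leaf_traversal(z, len(chosen))
    return WardClustering(
        sample_ids=chosen,
        linkage_=z,
        leaf_order=[chosen[i] for i in order],
        representatives=reps,
    )
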