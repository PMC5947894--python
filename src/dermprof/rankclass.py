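"""Gene ranking and multiclass classification of skin states.

Feature ranking is mRMR (minimum redundancy, maximum relevance) in the
difference form: the first gene maximizes the mutual information I(g;
class); each subsequent step picks the gene maximizing I(g; class) minus
the mean mutual information with the already-selected genes.  Mutual
information is estimated with k-nearest-neighbor estimators: the classic
continuous-continuous estimator for gene-gene redundancy and its
discrete-target adaptation (kth neighbor found within class, neighborhood
counted over all samples) for gene-class relevance.

Classification is a soft-margin linear SVM (C = 1), one-vs-one voting,
with features standardized on training folds only, assessed by stratified
10-fold and leave-one-out cross-validation.  Confusion matrices over the
7-state taxonomy collapse by block summation to the 3-state (carcinoma /
melanoma / healthy) and 2-state (tumor / healthy) taxonomies; collapsing
can only convert within-superstate errors into correct calls, so accuracy
never decreases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.base import BaseEstimator
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


DEFAULT_FOLD_SEED = 20180511


@dataclass(frozen=True)
class TaxonomyMap:
    """Maps between the 7-state, 3-state and 2-state skin taxonomies."""

    three_class: Mapping[str, str]
    two_class: Mapping[str, str]  # super-state -> {tumor, healthy}

    def collapse_label(self, label: str, levels: int) -> str:
        if levels == 7:
            return label
        three = self.three_class[label]
        if levels == 3:
            return three
        if levels == 2:
            return self.two_class[three]
        raise ValueError("levels must be 7, 3 or 2")

    def composed_two_class(self) -> dict[str, str]:
        return {k: self.two_class[v] for k, v in self.three_class.items()}


SKIN_TAXONOMY = TaxonomyMap(
    three_class={
        "BCC": "carcinoma",
        "SCC": "carcinoma",
        "MCC": "carcinoma",
        "PRIMEL": "melanoma",
        "METMEL": "melanoma",
        "NSK": "healthy",
        "NEV": "healthy",
    },
    two_class={"carcinoma": "tumor", "melanoma": "tumor", "healthy": "healthy"},
)


# ---------------------------------------------------------------------------
# mutual information


def _jitter(x: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return x + 1e-10 * np.maximum(1.0, np.std(x)) * rng.standard_normal(x.shape)


def _mi_cc(x: np.ndarray, y: np.ndarray, k: int) -> float:
    n = x.size
    z = np.column_stack([x, y])
    tree = cKDTree(z)
    # distance to the kth neighbor in the max norm (excluding self)
    dist, _ = tree.query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs = np.sort(x)
    ys = np.sort(y)
    # strictly-inside counts per marginal, excluding self
    nx = (
        np.searchsorted(xs, x + eps, side="left")
        - np.searchsorted(xs, x - eps, side="right")
        - 1
    )
    ny = (
        np.searchsorted(ys, y + eps, side="left")
        - np.searchsorted(ys, y - eps, side="right")
        - 1
    )
    mi = (
        digamma(k)
        + digamma(n)
        - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )
    return max(0.0, float(mi))


def _mi_cd(x: np.ndarray, y: np.ndarray, k: int) -> float:
    n = x.size
    labels, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    radius = np.empty(n)
    k_used = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for li, label in enumerate(labels):
        mask = inverse == li
        n_c = counts[li]
        if n_c < 2:
            keep[mask] = False
            warnings.warn(f"class {label!r} has a single sample; excluded from MI")
            continue
        k_c = min(k, n_c - 1)
        if k_c < k:
            warnings.warn(f"class {label!r} has {n_c} samples; k reduced to {k_c}")
        xc = x[mask]
        tree = cKDTree(xc[:, None])
        dist, _ = tree.query(xc[:, None], k=k_c + 1, p=np.inf)
        radius[mask] = np.nextafter(dist[:, -1], 0)
        k_used[mask] = k_c
    if not keep.any():
        return 0.0
    tree_all = cKDTree(x[:, None])
    m = np.asarray(
        tree_all.query_ball_point(
            x[keep, None], radius[keep], p=np.inf, return_length=True
        ),
        dtype=float,
    )
    m = np.maximum(m, 1.0)
    label_counts = counts[inverse[keep]]
    mi = (
        digamma(n)
        - np.mean(digamma(label_counts))
        + np.mean(digamma(k_used[keep]))
        - np.mean(digamma(m))
    )
    return max(0.0, float(mi))


def knn_mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    discrete_y: bool | None = None,
    jitter_seed: int = 0,
) -> float:
    """k-nearest-neighbor mutual information estimate in nats.

    Continuous-continuous uses the max-norm kth-neighbor estimator
    ``I = psi(k) + psi(N) - mean[psi(n_x + 1) + psi(n_y + 1)]``; with a
    discrete target, the kth neighbor is found within class and
    ``I = psi(N) - mean psi(N_class) + psi(k) - mean psi(m_i)`` with m_i
    counting all points inside that radius.  Estimates are clipped at 0 and
    a tiny seeded jitter breaks distance ties deterministically.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} observations")
    if discrete_y is None:
        discrete_y = not np.issubdtype(y.dtype, np.floating)
    x = _jitter(x, jitter_seed)
    if discrete_y:
        return _mi_cd(x, y, k)
    yc = _jitter(np.asarray(y, dtype=float), jitter_seed + 1)
    return _mi_cc(x, yc, k)


# ---------------------------------------------------------------------------
# mRMR ranking


@dataclass
class RankingResult:
    order: list[str]
    relevance: dict[str, float]
    steps: pd.DataFrame  # rank, gene, relevance, redundancy_mean, score


class MRMRRanker(BaseEstimator):
    """mRMR feature ranking (difference form) with k-NN mutual information.

    ``fit(X, y)`` with X of shape (n_samples, n_genes); the fitted
    ``ranking_`` lists all genes, ``order_`` their column indices.  The
    quotient (ratio) form is available via ``scheme='quotient'``.
    """

    def __init__(self, k_mi: int = 3, scheme: str = "difference", jitter_seed: int = 0):
        if scheme not in ("difference", "quotient"):
            raise ValueError("scheme must be 'difference' or 'quotient'")
        self.k_mi = k_mi
        self.scheme = scheme
        self.jitter_seed = jitter_seed

    def fit(self, X, y, gene_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with >= 1 feature")
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
        genes = list(map(str, gene_names))
        n_genes = len(genes)

        relevance = np.array(
            [
                knn_mutual_information(
                    X[:, j], y, k=self.k_mi, discrete_y=True,
                    jitter_seed=self.jitter_seed + j,
                )
                for j in range(n_genes)
            ]
        )
        redundancy_cache: dict[tuple[int, int], float] = {}

        def red(a: int, b: int) -> float:
            key = (min(a, b), max(a, b))
            if key not in redundancy_cache:
                redundancy_cache[key] = knn_mutual_information(
                    X[:, key[0]],
                    X[:, key[1]],
                    k=self.k_mi,
                    discrete_y=False,
                    jitter_seed=self.jitter_seed + 7919 + key[0] * n_genes + key[1],
                )
            return redundancy_cache[key]

        selected: list[int] = []
        records = []
        remaining = list(range(n_genes))
        while remaining:
            best_j, best_score, best_red = None, None, 0.0
            for j in sorted(remaining, key=lambda j: genes[j]):
                if selected:
                    mean_red = float(np.mean([red(j, s) for s in selected]))
                else:
                    mean_red = 0.0
                if self.scheme == "difference":
                    score = relevance[j] - mean_red
                else:
                    score = relevance[j] / (mean_red + 1e-12)
                if best_score is None or score > best_score + 1e-12:
                    best_j, best_score, best_red = j, score, mean_red
            selected.append(best_j)
            remaining.remove(best_j)
            records.append(
                {
                    "rank": len(selected),
                    "gene_symbol": genes[best_j],
                    "relevance": float(relevance[best_j]),
                    "redundancy_mean": best_red,
                    "score": float(best_score),
                }
            )
        self.order_ = selected
        self.ranking_ = [genes[j] for j in selected]
        self.relevance_ = dict(zip(genes, relevance.tolist()))
        self.steps_ = pd.DataFrame(records)
        return self

    def result(self) -> RankingResult:
        return RankingResult(
            order=list(self.ranking_),
            relevance=dict(self.relevance_),
            steps=self.steps_.copy(),
        )


def mrmr_rank(
    expression: pd.DataFrame,
    labels: Sequence[str],
    k_mi: int = 3,
    scheme: str = "difference",
    jitter_seed: int = 0,
) -> RankingResult:
    """Rank the genes of a genes x samples matrix by mRMR."""
    ranker = MRMRRanker(k_mi=k_mi, scheme=scheme, jitter_seed=jitter_seed)
    ranker.fit(
        expression.to_numpy().T,
        np.asarray(list(labels)),
        gene_names=list(expression.index),
    )
    return ranker.result()


# ---------------------------------------------------------------------------
# SVM cross-validation, taxonomy collapse, incremental curves


@dataclass
class CVEntry:
    scheme: str
    n_genes: int
    genes: list[str]
    confusion: pd.DataFrame  # true x predicted
    accuracy: float
    per_class_accuracy: dict[str, float]


def _confusion(y_true, y_pred, labels) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def _accuracy(confusion: pd.DataFrame) -> float:
    total = confusion.to_numpy().sum()
    return float(np.trace(confusion.to_numpy()) / total) if total else 0.0


def _per_class(confusion: pd.DataFrame) -> dict[str, float]:
    out = {}
    for label in confusion.index:
        row = confusion.loc[label]
        total = int(row.sum())
        out[str(label)] = float(row[label] / total) if total else np.nan
    return out


def svm_cross_validate(
    expression: pd.DataFrame,
    labels: Sequence[str],
    gene_subset: Sequence[str] | None = None,
    scheme: str = "kfold",
    n_folds: int = 10,
    seed: int = DEFAULT_FOLD_SEED,
    kernel: str = "linear",
    C: float = 1.0,
) -> CVEntry:
    """Cross-validated multiclass SVM on a gene subset.

    Linear soft-margin SVM (one-vs-one voting), features standardized with
    training-fold statistics only; stratified seeded folds for ``kfold``,
    exhaustive held-out singles for ``loo``.  Returns the accumulated
    confusion matrix and overall / per-class accuracies.
    """
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    if gene_subset is None:
        gene_subset = list(expression.index)
    if len(gene_subset) == 0:
        raise ValueError("gene subset must be non-empty")
    X = expression.loc[list(gene_subset)].to_numpy().T

    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, decision_function_shape="ovo")),
        ]
    )
    if scheme == "kfold":
        if counts.min() < n_folds:
            n_folds = int(counts.min())
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    elif scheme == "loo":
        cv = LeaveOneOut()
    else:
        raise ValueError("scheme must be 'kfold' or 'loo'")
    pred = cross_val_predict(model, X, y, cv=cv)
    confusion = _confusion(y, pred, classes)
    return CVEntry(
        scheme=scheme,
        n_genes=len(gene_subset),
        genes=list(gene_subset),
        confusion=confusion,
        accuracy=_accuracy(confusion),
        per_class_accuracy=_per_class(confusion),
    )


def collapse_taxonomy(
    confusion: pd.DataFrame, mapping: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Collapse a confusion matrix by summing super-state blocks.

    Entry (A, B) of the collapsed matrix is the sum of input entries over
    the member states of A and B; accuracy is trace / total.
    """
    unmapped = [l for l in confusion.index if l not in mapping]
    if unmapped:
        raise ValueError(f"labels without a taxonomy mapping: {unmapped}")
    supers = list(dict.fromkeys(mapping[l] for l in confusion.index))
    collapsed = pd.DataFrame(0, index=supers, columns=supers, dtype=int)
    for a in confusion.index:
        for b in confusion.columns:
            collapsed.loc[mapping[a], mapping[b]] += int(confusion.loc[a, b])
    return collapsed, _accuracy(collapsed)


@dataclass
class CVReport:
    """Accuracy curves over feature-subset sizes, schemes and taxonomies."""

    entries: dict[tuple[str, int], CVEntry] = field(default_factory=dict)
    taxonomy: TaxonomyMap = SKIN_TAXONOMY
    fold_seed: int = DEFAULT_FOLD_SEED

    def curve_table(self) -> pd.DataFrame:
        rows = []
        for (scheme, k), entry in sorted(self.entries.items()):
            mappable = all(l in self.taxonomy.three_class for l in entry.confusion.index)
            if mappable:
                three, acc3 = collapse_taxonomy(entry.confusion, self.taxonomy.three_class)
                _, acc2 = collapse_taxonomy(three, self.taxonomy.two_class)
            else:  # labels outside the skin taxonomy: no collapse defined
                acc3 = acc2 = np.nan
            row = {
                "scheme": scheme,
                "n_genes": k,
                "accuracy_7class": entry.accuracy,
                "accuracy_3class": acc3,
                "accuracy_2class": acc2,
            }
            for cls, acc in entry.per_class_accuracy.items():
                row[f"acc_{cls}"] = acc
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fold_seed": self.fold_seed,
            "entries": [
                {
                    "scheme": scheme,
                    "n_genes": k,
                    "genes": e.genes,
                    "accuracy": e.accuracy,
                    "per_class_accuracy": e.per_class_accuracy,
                    "confusion": {
                        "labels": list(e.confusion.index),
                        "matrix": e.confusion.to_numpy().tolist(),
                    },
                }
                for (scheme, k), e in sorted(self.entries.items())
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def incremental_curves(
    expression: pd.DataFrame,
    labels: Sequence[str],
    ranking: RankingResult | Sequence[str],
    schemes: Sequence[str] = ("loo", "kfold"),
    n_folds: int = 10,
    seed: int = DEFAULT_FOLD_SEED,
    taxonomy: TaxonomyMap = SKIN_TAXONOMY,
    kernel: str = "linear",
    C: float = 1.0,
) -> CVReport:
    """Evaluate the SVM on the top-k ranked genes for k = 1..len(ranking)."""
    order = ranking.order if isinstance(ranking, RankingResult) else list(ranking)
    missing = [g for g in order if g not in expression.index]
    if missing:
        raise ValueError(f"ranked genes absent from expression: {missing[:5]}")
    report = CVReport(taxonomy=taxonomy, fold_seed=seed)
    for k in range(1, len(order) + 1):
        subset = order[:k]
        for scheme in schemes:
            report.entries[(scheme, k)] = svm_cross_validate(
                expression,
                labels,
                subset,
                scheme=scheme,
                n_folds=n_folds,
                seed=seed,
                kernel=kernel,
                C=C,
            )
    return report
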