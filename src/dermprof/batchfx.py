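"""Batch-effect adjustment methods for merged multi-series expression data.

Six methods, each an sklearn-style transformer operating on a
samples x genes matrix with per-sample batch labels:

* ``MC``  — per-gene batch mean centering to the grand mean.
* ``EB``  — parametric empirical-Bayes location/scale adjustment: per-gene
  standardization, per-batch location (gamma) and scale (delta^2) estimates
  shrunk toward batch-level normal / inverse-gamma priors fitted by the
  method of moments, iterated to convergence.  Biological covariates are
  excluded by default (the adjuster sees only batch structure); an explicit
  ``protect`` option regresses class means out before estimating batch
  effects and restores them afterwards.
* ``MRS`` — median rank scores: per-batch gene medians are mapped, by rank,
  onto the gene-median quantiles of a reference batch (the largest).
* ``QD``  — per-sample equal-frequency quantile discretization into Q bins.
* ``GQ``  — per-gene cross-batch quantile mapping: each value is carried
  through its within-batch ECDF level to the pooled per-gene quantile
  function.
* ``NORDI`` — per-sample normal-model ternary discretization: iterative
  Grubbs outlier removal, then values beyond m +/- z * s map to +/-1, the
  rest to 0.

The two discretizers bound the attainable dynamic range (|LFC| <= 2 after
NORDI; <= Q-1 after QD), which is why they can return empty DEG sets at a
|LFC| >= 4 threshold regardless of the biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from dermprof.integrate import MergedSet

BATCH_METHODS = ("GQ", "EB", "NORDI", "QD", "MRS", "MC")

_EPS_SD = 1e-8


def _check_X_batches(X, batches, min_per_batch: int = 1):
    X = check_array(X, dtype=float, ensure_all_finite=True)
    batches = np.asarray(batches)
    if batches.shape[0] != X.shape[0]:
        raise ValueError(
            f"got {batches.shape[0]} batch labels for {X.shape[0]} samples"
        )
    labels, counts = np.unique(batches, return_counts=True)
    if counts.min() < min_per_batch:
        small = labels[counts < min_per_batch].tolist()
        raise ValueError(
            f"batches {small} have fewer than {min_per_batch} samples"
        )
    return X, batches, labels


class BatchAdjuster(TransformerMixin, BaseEstimator):
    """Base class: fit on (X, batch labels), transform sample-wise."""

    name: str = "?"

    def fit(self, X, y=None, **kwargs):
        self.fit_transform(X, y, **kwargs)
        return self

    def transform(self, X, batches=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit_transform(self, X, y=None, **kwargs):
        raise NotImplementedError


class MeanCenteringAdjuster(BatchAdjuster):
    """MC: per gene, subtract the batch mean and restore the grand mean."""

    name = "MC"

    def fit_transform(self, X, y=None, **kwargs):
        X, batches, labels = _check_X_batches(X, y, min_per_batch=2)
        self.grand_mean_ = X.mean(axis=0)
        self.batch_means_ = {
            b: X[batches == b].mean(axis=0) for b in labels
        }
        self.batches_ = labels
        return self.transform(X, batches)

    def transform(self, X, batches=None):
        check_is_fitted(self, "grand_mean_")
        X = check_array(X, dtype=float)
        if batches is None:
            raise ValueError("MC requires batch labels at transform time")
        batches = np.asarray(batches)
        out = np.empty_like(X)
        for b in np.unique(batches):
            mask = batches == b
            out[mask] = X[mask] - self.batch_means_[b] + self.grand_mean_
        return out


class EmpiricalBayesAdjuster(BatchAdjuster):
    """EB: parametric empirical-Bayes location/scale batch adjustment.

    Per gene g, values are standardized, ``Z = (x - alpha_g) / sigma_g``,
    with the grand mean ``alpha_g`` and pooled SD ``sigma_g`` (or, with
    ``protect=True`` and class labels supplied, with per-class fitted means
    and residual SD).  Per batch i the location ``gamma_ig`` (mean of Z) and
    scale ``delta_ig^2`` (variance of Z) are shrunk toward normal /
    inverse-gamma priors whose hyperparameters come from the method of
    moments across genes, iterating

        gamma* = (n_i tau^2 gamma_hat + delta*^2 gamma_bar)
                 / (n_i tau^2 + delta*^2)
        delta*^2 = (theta + 0.5 sum_s (Z - gamma*)^2) / (n_i/2 + lambda - 1)

    to convergence, then restoring ``x* = sigma_g (Z - gamma*) / delta* +
    alpha_g`` (plus the protected class fit, if any).
    """

    name = "EB"

    def __init__(self, tol: float = 1e-6, max_iter: int = 200, protect: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.protect = protect

    def fit_transform(self, X, y=None, classes=None, **kwargs):
        X, batches, labels = _check_X_batches(X, y, min_per_batch=2)
        n, g = X.shape

        if self.protect:
            if classes is None:
                raise ValueError("protect=True requires class labels")
            classes = np.asarray(classes)
            class_means = {c: X[classes == c].mean(axis=0) for c in np.unique(classes)}
            fitted = np.vstack([class_means[c] for c in classes])
        else:
            fitted = np.broadcast_to(X.mean(axis=0), X.shape)
        self.alpha_ = X.mean(axis=0)
        resid = X - fitted
        # pooled within-batch SD: batch-mean differences are the effect to
        # remove and must not inflate the standardization scale
        sse_within = np.zeros(X.shape[1])
        for b in labels:
            rb = resid[batches == b]
            sse_within += ((rb - rb.mean(axis=0)) ** 2).sum(axis=0)
        sigma = np.sqrt(sse_within / (n - len(labels)))
        self.sigma_ = np.maximum(sigma, _EPS_SD)

        Z = resid / self.sigma_
        self.gamma_star_: dict = {}
        self.delta_star_: dict = {}
        self.prior_: dict = {}
        out = np.empty_like(X)
        for b in labels:
            mask = batches == b
            n_i = int(mask.sum())
            Zb = Z[mask]
            gamma_hat = Zb.mean(axis=0)
            delta2_hat = Zb.var(axis=0, ddof=1)
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            v = delta2_hat.mean()
            s2 = delta2_hat.var(ddof=1)
            if s2 <= 0:
                lam, theta = 2.0 + _EPS_SD, v  # flat-ish prior fallback
            else:
                lam = (2.0 * s2 + v * v) / s2
                theta = (v * s2 + v**3) / s2
            gamma_star = gamma_hat.copy()
            delta2_star = delta2_hat.copy()
            for _ in range(self.max_iter):
                g_new = (n_i * tau2 * gamma_hat + delta2_star * gamma_bar) / (
                    n_i * tau2 + delta2_star
                )
                sse = ((Zb - g_new) ** 2).sum(axis=0)
                d_new = (theta + 0.5 * sse) / (n_i / 2.0 + lam - 1.0)
                change = max(
                    np.max(np.abs(g_new - gamma_star)),
                    np.max(np.abs(d_new - delta2_star)),
                )
                gamma_star, delta2_star = g_new, d_new
                if change < self.tol:
                    break
            self.gamma_star_[b] = gamma_star
            self.delta_star_[b] = np.sqrt(np.maximum(delta2_star, _EPS_SD))
            self.prior_[b] = {
                "gamma_bar": float(gamma_bar),
                "tau2": float(tau2),
                "lambda": float(lam),
                "theta": float(theta),
            }
            out[mask] = (
                self.sigma_ * (Zb - gamma_star) / self.delta_star_[b]
                + fitted[mask]
            )
        self.batches_ = labels
        return out

    def transform(self, X, batches=None):
        check_is_fitted(self, "gamma_star_")
        X = check_array(X, dtype=float)
        if batches is None:
            raise ValueError("EB requires batch labels at transform time")
        if self.protect:
            raise ValueError("transform on new data unsupported with protect=True")
        batches = np.asarray(batches)
        Z = (X - self.alpha_) / self.sigma_
        out = np.empty_like(X)
        for b in np.unique(batches):
            mask = batches == b
            out[mask] = (
                self.sigma_ * (Z[mask] - self.gamma_star_[b]) / self.delta_star_[b]
                + self.alpha_
            )
        return out


class MedianRankScoresAdjuster(BatchAdjuster):
    """MRS: map per-batch gene medians onto reference-batch median quantiles.

    The reference is the largest batch (ties broken lexicographically).  For
    a non-reference batch b, gene g with batch median m and within-batch
    median rank r: ``x* = x - m + q_ref(r)`` where ``q_ref`` interpolates the
    sorted reference gene medians at rank r.
    """

    name = "MRS"

    def fit_transform(self, X, y=None, **kwargs):
        X, batches, labels = _check_X_batches(X, y, min_per_batch=2)
        counts = {b: int((batches == b).sum()) for b in labels}
        self.reference_batch_ = sorted(labels, key=lambda b: (-counts[b], str(b)))[0]
        ref_medians = np.median(X[batches == self.reference_batch_], axis=0)
        self.ref_sorted_ = np.sort(ref_medians)
        self.batch_medians_ = {}
        self.batch_shift_ = {}
        g = X.shape[1]
        positions = np.arange(1, g + 1)
        for b in labels:
            med = np.median(X[batches == b], axis=0)
            self.batch_medians_[b] = med
            if b == self.reference_batch_:
                self.batch_shift_[b] = np.zeros(g)
            else:
                ranks = stats.rankdata(med)
                mapped = np.interp(ranks, positions, self.ref_sorted_)
                self.batch_shift_[b] = mapped - med
        self.batches_ = labels
        return self.transform(X, batches)

    def transform(self, X, batches=None):
        check_is_fitted(self, "batch_shift_")
        X = check_array(X, dtype=float)
        if batches is None:
            raise ValueError("MRS requires batch labels at transform time")
        batches = np.asarray(batches)
        out = np.empty_like(X)
        for b in np.unique(batches):
            mask = batches == b
            out[mask] = X[mask] + self.batch_shift_[b]
        return out


class QuantileDiscretizationAdjuster(BatchAdjuster):
    """QD: per sample, equal-frequency discretization into Q bins (1..Q)."""

    name = "QD"

    def __init__(self, n_bins: int = 16):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.n_bins = n_bins

    def fit_transform(self, X, y=None, **kwargs):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self.transform(X)

    def transform(self, X, batches=None):
        X = check_array(X, dtype=float)
        g = X.shape[1]
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            ranks = stats.rankdata(X[i], method="ordinal")
            out[i] = np.floor((ranks - 1) * self.n_bins / g) + 1
        return out


class GeneQuantilesAdjuster(BatchAdjuster):
    """GQ: per gene, within-batch ECDF level mapped through pooled quantiles.

    Each value's ECDF level within its batch, ``u = (rank - 0.5) / n_b``, is
    carried through the pooled (all-batch) empirical quantile function of
    the same gene.
    """

    name = "GQ"

    def fit_transform(self, X, y=None, **kwargs):
        X, batches, labels = _check_X_batches(X, y, min_per_batch=2)
        self.pooled_sorted_ = np.sort(X, axis=0)  # per gene
        self.batches_ = labels
        return self.transform(X, batches)

    def transform(self, X, batches=None):
        check_is_fitted(self, "pooled_sorted_")
        X = check_array(X, dtype=float)
        if batches is None:
            raise ValueError("GQ requires batch labels at transform time")
        batches = np.asarray(batches)
        n_pool = self.pooled_sorted_.shape[0]
        out = np.empty_like(X)
        for b in np.unique(batches):
            mask = batches == b
            Xb = X[mask]
            n_b = Xb.shape[0]
            for j in range(X.shape[1]):
                u = (stats.rankdata(Xb[:, j]) - 0.5) / n_b
                out[mask, j] = np.quantile(
                    self.pooled_sorted_[:, j], u, method="linear"
                )
        return out


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1.0) / np.sqrt(n) * np.sqrt(t * t / (n - 2.0 + t * t))


class NordiAdjuster(BatchAdjuster):
    """NORDI: per-sample normal-model ternary discretization.

    Per sample: iteratively remove Grubbs outliers at ``alpha_out``; with
    the retained mean m and SD s, map values above ``m + z s`` to +1, below
    ``m - z s`` to -1, the rest to 0, where ``z = z_{1 - alpha_disc/2}``.
    """

    name = "NORDI"

    def __init__(self, alpha_out: float = 0.05, alpha_disc: float = 0.05):
        for a in (alpha_out, alpha_disc):
            if not 0 < a < 1:
                raise ValueError("alpha parameters must lie in (0, 1)")
        self.alpha_out = alpha_out
        self.alpha_disc = alpha_disc

    def fit_transform(self, X, y=None, **kwargs):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self.transform(X)

    def transform(self, X, batches=None):
        X = check_array(X, dtype=float)
        z = stats.norm.ppf(1.0 - self.alpha_disc / 2.0)
        out = np.zeros_like(X)
        for i in range(X.shape[0]):
            vals = X[i].copy()
            retained = vals.copy()
            while retained.size >= 3:
                m = retained.mean()
                s = retained.std(ddof=1)
                if s <= 0:
                    break
                dev = np.abs(retained - m)
                idx = int(np.argmax(dev))
                if dev[idx] / s > _grubbs_critical(retained.size, self.alpha_out):
                    retained = np.delete(retained, idx)
                else:
                    break
            m = retained.mean()
            s = retained.std(ddof=1) if retained.size > 1 else 0.0
            if s > 0:
                out[i] = np.where(
                    vals > m + z * s, 1.0, np.where(vals < m - z * s, -1.0, 0.0)
                )
        return out


_ADJUSTERS = {
    "MC": MeanCenteringAdjuster,
    "EB": EmpiricalBayesAdjuster,
    "MRS": MedianRankScoresAdjuster,
    "QD": QuantileDiscretizationAdjuster,
    "GQ": GeneQuantilesAdjuster,
    "NORDI": NordiAdjuster,
}


def make_batch_adjuster(name: str, **params) -> BatchAdjuster:
    """Instantiate one of the six adjusters by name (GQ, EB, NORDI, QD, MRS, MC)."""
    if name not in _ADJUSTERS:
        raise ValueError(f"unknown batch method {name!r}; expected one of {BATCH_METHODS}")
    return _ADJUSTERS[name](**params)


def apply_batch_adjustment(
    merged: MergedSet, method: str | BatchAdjuster, **params
) -> MergedSet:
    """Apply a batch adjustment to a merged set, series = batch.

    Returns a new :class:`MergedSet` with the same shape and annotations and
    the method recorded in provenance.
    """
    adjuster = method if isinstance(method, BatchAdjuster) else make_batch_adjuster(method, **params)
    X = merged.expression.to_numpy().T  # samples x genes
    batches = merged.series_labels()
    kwargs = {}
    if isinstance(adjuster, EmpiricalBayesAdjuster) and adjuster.protect:
        kwargs["classes"] = merged.class_labels()
    adjusted = adjuster.fit_transform(X, batches, **kwargs)
    return MergedSet(
        expression=pd.DataFrame(
            adjusted.T, index=merged.expression.index, columns=merged.expression.columns
        ),
        samples=list(merged.samples),
        union_method=merged.union_method,
        batch_method=adjuster.name,
        source_series=list(merged.source_series),
    )
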