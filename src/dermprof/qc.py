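"""Per-series array quality control.

Screens each series for outlying arrays with three complementary metrics,
applied iteratively until no further sample is removed:

* mean inter-sample distance (mean absolute difference of intensities),
* the two-sample Kolmogorov–Smirnov statistic ``K_a`` of each array against
  the pooled intensities of the remaining arrays,
* Hoeffding's D statistic of dependence between the MA-plot coordinates of
  each array against the gene-wise median pseudo-array.

Distance and KS flags use the upper Tukey fence (Q3 + 1.5 IQR) over the
per-round metric values; Hoeffding's D flags arrays whose A-vs-M dependence
exceeds a fixed threshold (default 0.15).  The conventional printed rule
"D < 0.15" describes the *acceptable* region; the screen therefore flags
arrays with D above the threshold, and the report records that reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from dermprof.synthio import SeriesBundle

MIN_SAMPLES = 6


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic of bivariate dependence, scaled to [-0.5, 1].

    Uses mid-ranks ``R_i``, ``S_i`` and the bivariate rank
    ``Q_i = 1 + #{j != i: x_j < x_i and y_j < y_i}``, counting one half for
    each tie in exactly one coordinate (with the other strictly below) and
    one quarter for each tie in both coordinates.  Then::

        D1 = sum (Q_i - 1)(Q_i - 2)
        D2 = sum (R_i - 1)(R_i - 2)(S_i - 1)(S_i - 2)
        D3 = sum (R_i - 2)(S_i - 2)(Q_i - 1)
        D  = 30 * [(n-2)(n-3) D1 + D2 - 2(n-2) D3] / [n(n-1)(n-2)(n-3)(n-4)]

    D is 0 in expectation under independence and grows with dependence.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 5:
        raise ValueError("hoeffding_d requires n >= 5")

    r = stats.rankdata(x)  # mid-ranks
    s = stats.rankdata(y)

    lt_x = x[None, :] < x[:, None]  # [i, j] : x_j < x_i
    eq_x = x[None, :] == x[:, None]
    lt_y = y[None, :] < y[:, None]
    eq_y = y[None, :] == y[:, None]
    np.fill_diagonal(eq_x, False)  # j != i
    np.fill_diagonal(eq_y, False)

    q = (
        1.0
        + (lt_x & lt_y).sum(axis=1)
        + 0.5 * ((eq_x & lt_y) | (lt_x & eq_y)).sum(axis=1)
        + 0.25 * (eq_x & eq_y).sum(axis=1)
    )

    d1 = np.sum((q - 1.0) * (q - 2.0))
    d2 = np.sum((r - 1.0) * (r - 2.0) * (s - 1.0) * (s - 2.0))
    d3 = np.sum((r - 2.0) * (s - 2.0) * (q - 1.0))
    denom = n * (n - 1.0) * (n - 2.0) * (n - 3.0) * (n - 4.0)
    return float(30.0 * ((n - 2.0) * (n - 3.0) * d1 + d2 - 2.0 * (n - 2.0) * d3) / denom)


def ks_statistic(sample: np.ndarray, pool: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic sup_t |ECDF_sample - ECDF_pool|."""
    sample = np.asarray(sample, dtype=float).ravel()
    pool = np.asarray(pool, dtype=float).ravel()
    if sample.size == 0 or pool.size == 0:
        raise ValueError("ks_statistic requires non-empty inputs")
    return float(stats.ks_2samp(sample, pool, method="asymp").statistic)


@dataclass
class QCRound:
    distance: dict[str, float]
    ks: dict[str, float]
    hoeffding: dict[str, float]
    flags: dict[str, list[str]]  # metric -> flagged sample ids
    removed: list[str]


@dataclass
class QCReport:
    """Per-series outlier-screening report."""

    series_id: str
    rounds: list[QCRound] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    kept_samples: list[str] = field(default_factory=list)
    status: str = "ok"  # 'ok' or 'too_few_samples'
    d_threshold: float = 0.15
    note: str = (
        "Hoeffding screen: arrays are acceptable when D < threshold; "
        "arrays with D above the threshold are flagged."
    )

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "series_id": self.series_id,
            "status": self.status,
            "d_threshold": self.d_threshold,
            "removed_samples": self.removed_samples,
            "kept_samples": self.kept_samples,
            "note": self.note,
            "rounds": [
                {
                    "distance": r.distance,
                    "ks": r.ks,
                    "hoeffding": r.hoeffding,
                    "flags": r.flags,
                    "removed": r.removed,
                }
                for r in self.rounds
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def metric_table(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds, start=1):
            for sid in r.distance:
                rows.append(
                    {
                        "round": i,
                        "sample_id": sid,
                        "distance": r.distance[sid],
                        "ks": r.ks[sid],
                        "hoeffding": r.hoeffding[sid],
                        "removed": sid in r.removed,
                    }
                )
        return pd.DataFrame(rows)


def _tukey_upper_fence(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def qc_screen(
    bundle: SeriesBundle,
    d_threshold: float = 0.15,
    max_rounds: int = 10,
    flag_rule: str = "majority",
) -> QCReport:
    """Iteratively screen a series for outlier arrays.

    Per round each remaining array receives a distance score, a KS ``K_a``
    statistic against the pooled intensities of the other arrays, and a
    Hoeffding D statistic of its MA-plot coordinates against the gene-wise
    median pseudo-array.  Arrays flagged by at least two metrics
    (``flag_rule='majority'``; use ``'any'`` for a single-metric rule) are
    removed; screening repeats until no removal, ``max_rounds``, or the
    series shrinking below six arrays (reported as ``too_few_samples``).
    """
    from dermprof.integrate import ensure_log2_scale

    if flag_rule not in ("majority", "any"):
        raise ValueError("flag_rule must be 'majority' or 'any'")
    if bundle.expression.shape[1] < MIN_SAMPLES:
        raise ValueError(
            f"{bundle.series_id}: qc_screen needs >= {MIN_SAMPLES} samples, "
            f"got {bundle.expression.shape[1]}"
        )

    x = ensure_log2_scale(bundle).expression
    report = QCReport(series_id=bundle.series_id, d_threshold=d_threshold)
    current = list(x.columns)

    for _ in range(max_rounds):
        if len(current) < MIN_SAMPLES:
            report.status = "too_few_samples"
            break
        sub = x[current].to_numpy()
        n = len(current)

        # (a) mean inter-sample distance
        diffs = np.mean(np.abs(sub[:, :, None] - sub[:, None, :]), axis=0)
        d_scores = (diffs.sum(axis=1)) / (n - 1)
        d_fence = _tukey_upper_fence(d_scores)
        d_flags = [current[i] for i in range(n) if d_scores[i] > d_fence]

        # (b) KS statistic of each array vs pooled others
        k_scores = np.empty(n)
        for i in range(n):
            pool = sub[:, np.arange(n) != i].ravel()
            k_scores[i] = ks_statistic(sub[:, i], pool)
        k_fence = _tukey_upper_fence(k_scores)
        k_flags = [current[i] for i in range(n) if k_scores[i] > k_fence]

        # (c) Hoeffding D of (A, M) vs the median pseudo-array
        pseudo = np.median(sub, axis=1)
        h_scores = np.empty(n)
        for i in range(n):
            a = 0.5 * (sub[:, i] + pseudo)
            m = sub[:, i] - pseudo
            h_scores[i] = hoeffding_d(a, m)
        h_flags = [current[i] for i in range(n) if h_scores[i] > d_threshold]

        votes: dict[str, int] = {}
        for flagged in (d_flags, k_flags, h_flags):
            for sid in flagged:
                votes[sid] = votes.get(sid, 0) + 1
        need = 2 if flag_rule == "majority" else 1
        removed = sorted(s for s, v in votes.items() if v >= need)

        report.rounds.append(
            QCRound(
                distance=dict(zip(current, d_scores.tolist())),
                ks=dict(zip(current, k_scores.tolist())),
                hoeffding=dict(zip(current, h_scores.tolist())),
                flags={"distance": d_flags, "ks": k_flags, "hoeffding": h_flags},
                removed=removed,
            )
        )
        if not removed:
            break
        report.removed_samples.extend(removed)
        current = [s for s in current if s not in removed]
        if len(current) < MIN_SAMPLES:
            report.status = "too_few_samples"
            break

    report.kept_samples = current
    return report


def apply_qc(bundle: SeriesBundle, report: QCReport) -> SeriesBundle:
    """Return a copy of ``bundle`` with the report's removed samples dropped."""
    keep = [a for a in bundle.samples if a.sample_id not in set(report.removed_samples)]
    return SeriesBundle(
        series_id=bundle.series_id,
        expression=bundle.expression[[a.sample_id for a in keep]],
        probe_map=dict(bundle.probe_map),
        samples=keep,
        scale=bundle.scale,
    )
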