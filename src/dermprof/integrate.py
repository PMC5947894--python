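"""Scale homogenization, probe summarization and symbol-intersection merging.

Series arrive either on a log2 scale or as linear intensities of varying
bit depth.  ``ensure_log2_scale`` homogenizes linear series to a 16-bit
dynamic range and takes log2; ``summarize_probes`` collapses probes to gene
symbols by a union method (mean or median over a gene's probes); and
``merge_series`` joins several gene-level series on the intersection of
their gene panels, the only genes quantifiable on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from dermprof.synthio import LINEAR16_MAX, SampleAnnotation, SeriesBundle

#: log2 microarray data never exceeds ~20; anything above this is linear.
AUTO_DETECT_LINEAR_MAX = 30.0


@dataclass
class MergedSet:
    """Gene x sample matrix merged across series, with provenance."""

    expression: pd.DataFrame  # genes x samples, log2 units (pre-discretization)
    samples: list[SampleAnnotation]
    union_method: str
    batch_method: str | None = None
    source_series: list[str] = field(default_factory=list)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.expression.index)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": a.sample_id,
                    "series_id": a.series_id,
                    "class_label": a.class_label,
                    "country": a.country,
                    "platform": a.platform,
                    "technology": a.technology,
                }
                for a in self.samples
            ]
        )

    def class_labels(self) -> np.ndarray:
        return np.asarray([a.class_label for a in self.samples], dtype=object)

    def series_labels(self) -> np.ndarray:
        return np.asarray([a.series_id for a in self.samples], dtype=object)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.expression.copy()
        out.index.name = "gene_symbol"
        out.to_csv(directory / "expression.tsv", sep="\t", float_format="%.6f")
        self.sample_frame().to_csv(directory / "samples.tsv", sep="\t", index=False)
        (directory / "provenance.json").write_text(
            json.dumps(
                {
                    "union_method": self.union_method,
                    "batch_method": self.batch_method,
                    "source_series": self.source_series,
                },
                indent=2,
            )
        )


def ensure_log2_scale(bundle: SeriesBundle, auto_detect: bool = False) -> SeriesBundle:
    """Return ``bundle`` on a log2 scale; idempotent for log2 inputs.

    Linear series (``scale='linear16'``, or any series whose maximum exceeds
    30 when ``auto_detect`` is on) are rescaled so their maximum equals
    65535 and transformed ``v -> log2(v + 1)``, giving values in [0, 16].
    The +1 offset keeps zero intensities finite.
    """
    x = bundle.expression
    is_linear = bundle.scale == "linear16" or (
        auto_detect and float(x.to_numpy().max()) > AUTO_DETECT_LINEAR_MAX
    )
    if not is_linear:
        return bundle
    v = x.to_numpy(dtype=float)
    if v.min() < 0:
        raise ValueError(
            f"{bundle.series_id}: negative values on a linear-scale series"
        )
    v = v * (LINEAR16_MAX / v.max())
    logged = np.log2(v + 1.0)
    return SeriesBundle(
        series_id=bundle.series_id,
        expression=pd.DataFrame(logged, index=x.index, columns=x.columns),
        probe_map=dict(bundle.probe_map),
        samples=list(bundle.samples),
        scale="log2",
    )


def summarize_probes(bundle: SeriesBundle, union_method: str = "mean") -> pd.DataFrame:
    """Collapse probes to gene symbols by the mean or median over probes.

    Requires a log2-scale bundle with every probe mapped; returns a gene x
    sample matrix with genes in lexicographic order.
    """
    if union_method not in ("mean", "median"):
        raise ValueError("union_method must be 'mean' or 'median'")
    if bundle.scale != "log2":
        raise ValueError(
            f"{bundle.series_id}: summarize_probes requires log2 scale "
            f"(got {bundle.scale!r}); apply ensure_log2_scale first"
        )
    unmapped = [p for p in bundle.expression.index if p not in bundle.probe_map]
    if unmapped:
        raise ValueError(f"{bundle.series_id}: unmapped probes: {unmapped[:10]}")
    genes = pd.Series(
        [bundle.probe_map[p] for p in bundle.expression.index],
        index=bundle.expression.index,
    )
    grouped = bundle.expression.groupby(genes)
    table = grouped.mean() if union_method == "mean" else grouped.median()
    return table.sort_index()


def merge_series(
    gene_tables: Sequence[tuple[pd.DataFrame, Sequence[SampleAnnotation]]],
    union_method: str = "mean",
) -> MergedSet:
    """Merge >= 2 gene-level series on the intersection of gene symbols.

    Samples are concatenated, ordered by (series_id, sample_id); an empty
    gene intersection raises with the per-series panel sizes.
    """
    if len(gene_tables) < 2:
        raise ValueError("merge_series requires at least 2 series")
    common: set[str] | None = None
    for table, _ in gene_tables:
        common = set(table.index) if common is None else common & set(table.index)
    assert common is not None
    if not common:
        sizes = [len(t.index) for t, _ in gene_tables]
        raise ValueError(
            f"empty gene intersection across {len(gene_tables)} series "
            f"(panel sizes: {sizes})"
        )
    genes = sorted(common)

    annotations: list[SampleAnnotation] = []
    for _, ann in gene_tables:
        annotations.extend(ann)
    annotations.sort(key=lambda a: (a.series_id, a.sample_id))
    order = [a.sample_id for a in annotations]

    merged = pd.concat([t.loc[genes] for t, _ in gene_tables], axis=1)[order]
    values = merged.to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("merged expression contains non-finite values")
    return MergedSet(
        expression=merged,
        samples=annotations,
        union_method=union_method,
        source_series=sorted({a.series_id for a in annotations}),
    )


def summarize_and_merge(
    bundles: Sequence[SeriesBundle], union_method: str = "mean"
) -> MergedSet:
    """Convenience: log2-homogenize, probe-summarize and merge bundles."""
    tables = []
    for b in bundles:
        logged = ensure_log2_scale(b)
        tables.append((summarize_probes(logged, union_method), logged.samples))
    return merge_series(tables, union_method=union_method)


def quantile_normalize_within(table: pd.DataFrame) -> pd.DataFrame:
    """Optional within-series quantile normalization (columns to a common
    distribution, the row-mean of the sorted columns).  Off by default in
    the pipeline; offered as a pre-merge smoothing step."""
    ranks = table.rank(axis=0, method="average")
    sorted_vals = np.sort(table.to_numpy(), axis=0)
    reference = sorted_vals.mean(axis=1)
    n = table.shape[0]
    positions = np.arange(1, n + 1)
    out = np.empty_like(table.to_numpy())
    for j in range(table.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), positions, reference)
    return pd.DataFrame(out, index=table.index, columns=table.columns)
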