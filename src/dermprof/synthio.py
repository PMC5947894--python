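"""Synthetic multi-series expression studies with known ground truth.

Real integrative studies of this kind pool many public microarray series,
each deposited by a different lab on its own platform and containing only a
subset of the biological classes of interest.  The generator here emulates
that structure: several series (= batches) drawing on platform-specific gene
panels with a guaranteed shared core, multiple probes per gene, additive and
multiplicative series-level batch effects, series emitted either on a log2
scale or on a linear 16-bit intensity scale, per-series country labels, and
a set of planted differentially expressed genes whose class-mean shifts are
recorded as ground truth.

The on-disk "series bundle" format is three TSV files per series
(``expression.tsv``, ``probes.tsv``, ``samples.tsv``) so every downstream
stage is testable without any external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The seven skin states of the study taxonomy: three carcinomas (basal
#: cell, squamous cell, Merkel cell), two melanomas (primary, metastatic)
#: and two healthy states (normal skin, nevus).
SKIN_STATES: tuple[str, ...] = (
    "BCC",
    "SCC",
    "MCC",
    "PRIMEL",
    "METMEL",
    "NSK",
    "NEV",
)

DEFAULT_COUNTRIES: tuple[str, ...] = (
    "USA",
    "Deutschland",
    "Australia",
    "Netherlands",
    "United Kingdom",
    "South Korea",
    "Finland",
)

LINEAR16_MAX = 65535.0


class BundleFormatError(ValueError):
    """A series bundle on disk violates the expected schema."""


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic multi-series study.

    Units are log2 expression throughout; ``planted_effect`` is the minimal
    class-mean shift (log2 fold change) carried by each planted gene.
    """

    n_series: int = 8
    classes: tuple[str, ...] = SKIN_STATES
    classes_per_series: tuple[int, int] = (5, 7)
    samples_per_class_per_series: tuple[int, int] = (10, 16)
    #: relative class frequencies (clinical availability differs sharply
    #: between skin states); mean-normalized internally, so the base range
    #: above describes a class of average frequency
    class_weights: tuple[float, ...] = (43, 84, 33, 118, 118, 250, 32)
    n_genes_global: int = 800
    panel_fraction: float = 0.85
    core_fraction: float = 0.70
    probes_per_gene: tuple[int, int] = (1, 3)
    n_planted_deg: int = 20
    planted_effect: float = 5.0
    planted_class_spread: float = 2.0
    batch_sd_add: float = 1.0
    batch_sd_mult: float = 0.1
    noise_sd: float = 0.5
    linear_scale_fraction: float = 0.25
    countries: tuple[str, ...] = DEFAULT_COUNTRIES
    seed: int = 0

    def validate(self) -> None:
        if self.n_series < 2:
            raise ValueError("need at least 2 series")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        lo, hi = self.classes_per_series
        if not (1 <= lo <= hi <= len(self.classes)):
            raise ValueError("classes_per_series out of range")
        slo, shi = self.samples_per_class_per_series
        if not (1 <= slo <= shi):
            raise ValueError("samples_per_class_per_series out of range")
        if int(self.core_fraction * self.n_genes_global) < 1:
            raise ValueError("core_fraction * n_genes_global must be >= 1")
        if not (0 < self.panel_fraction <= 1 and 0 < self.core_fraction <= self.panel_fraction):
            raise ValueError("need 0 < core_fraction <= panel_fraction <= 1")
        for name in ("batch_sd_add", "batch_sd_mult", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_effect <= 0:
            raise ValueError("planted_effect must be > 0")
        if self.n_planted_deg > int(self.core_fraction * self.n_genes_global):
            raise ValueError("cannot plant more DEGs than core genes")
        if not (0 <= self.linear_scale_fraction <= 1):
            raise ValueError("linear_scale_fraction must be in [0, 1]")
        if len(self.class_weights) != len(self.classes):
            raise ValueError("class_weights must match the class list")
        if min(self.class_weights) <= 0:
            raise ValueError("class_weights must be positive")
        # anchor scheme places 3 fixed classes per series; every class must
        # land in >= 2 series and every series must fit its anchors
        n_anchor = min(3, len(self.classes))
        if lo < n_anchor:
            raise ValueError(
                f"classes_per_series minimum must be >= {n_anchor} (anchor classes)"
            )
        if self.n_series * n_anchor < 2 * len(self.classes):
            raise ValueError(
                "study capacity too small: every class must appear in >= 2 series"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    series_id: str
    class_label: str
    country: str
    platform: str
    technology: str  # 'A' (Affymetrix-like) or 'I' (Illumina-like)


@dataclass
class SeriesBundle:
    """One series: probe-level expression plus probe map and annotations."""

    series_id: str
    expression: pd.DataFrame  # probes x samples
    probe_map: dict[str, str]  # probe_id -> gene symbol
    samples: list[SampleAnnotation]
    scale: str  # 'log2' or 'linear16'

    def validate(self) -> None:
        x = self.expression.to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{self.series_id}: expression contains non-finite values")
        missing = [p for p in self.expression.index if p not in self.probe_map]
        if missing:
            raise ValueError(
                f"{self.series_id}: probes missing from probe map: {missing[:5]}"
            )
        if len(self.samples) != self.expression.shape[1]:
            raise ValueError(
                f"{self.series_id}: {len(self.samples)} annotations for "
                f"{self.expression.shape[1]} expression columns"
            )
        if self.scale not in ("log2", "linear16"):
            raise ValueError(f"{self.series_id}: unknown scale {self.scale!r}")
        if self.scale == "linear16" and (x.min() < 0 or x.max() > LINEAR16_MAX):
            raise ValueError(
                f"{self.series_id}: linear16 values must lie in [0, {LINEAR16_MAX:.0f}]"
            )

    def sample_classes(self) -> pd.Series:
        return pd.Series(
            [a.class_label for a in self.samples],
            index=[a.sample_id for a in self.samples],
        )


@dataclass
class GroundTruth:
    """Generative quantities of a synthetic study.

    ``class_effects`` holds the class-mean shifts beta[g, k] (log2 units);
    non-planted genes have all-zero rows.  ``batch_add``/``batch_mult`` are
    the per-gene additive shifts gamma[g, b] and noise scale factors
    delta[g, b] of each series, and ``baseline_means`` the per-gene mu[g].
    """

    planted_deg_symbols: set[str]
    class_effects: pd.DataFrame  # genes x classes
    batch_add: pd.DataFrame  # genes x series
    batch_mult: pd.DataFrame  # genes x series
    baseline_means: pd.Series  # per gene

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_deg_symbols": sorted(self.planted_deg_symbols),
            "class_effects": self.class_effects.to_dict(orient="index"),
            "batch_add": self.batch_add.to_dict(orient="index"),
            "batch_mult": self.batch_mult.to_dict(orient="index"),
            "baseline_means": self.baseline_means.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_deg_symbols=set(payload["planted_deg_symbols"]),
            class_effects=pd.DataFrame.from_dict(payload["class_effects"], orient="index"),
            batch_add=pd.DataFrame.from_dict(payload["batch_add"], orient="index"),
            batch_mult=pd.DataFrame.from_dict(payload["batch_mult"], orient="index"),
            baseline_means=pd.Series(payload["baseline_means"]),
        )


def _child_seed(root: int, index: int) -> int:
    # fixed arithmetic so adding a series never perturbs earlier ones
    return (root * 100_003 + 7_919 * (index + 1)) % (2**31 - 1)


def _series_classes(
    rng: np.random.Generator, config: StudyConfig, index: int
) -> list[str]:
    """Class subset of one series: fixed cyclic anchors plus random extras.

    Three anchor classes per series come from a fixed cyclic walk over the
    class list (slots 3i, 3i+1, 3i+2 of series i), so every class is
    guaranteed in >= 2 series and the subset of series i never depends on
    how many series follow it; the remaining capacity is drawn from the
    series' own child RNG.
    """
    classes = list(config.classes)
    k = len(classes)
    n_anchor = min(3, k)
    cap = int(rng.integers(config.classes_per_series[0], config.classes_per_series[1] + 1))
    chosen: list[str] = []
    for r in range(n_anchor):
        c = classes[(n_anchor * index + r) % k]
        if c not in chosen:
            chosen.append(c)
    pool = [c for c in classes if c not in chosen]
    extra = cap - len(chosen)
    if extra > 0 and pool:
        picks = rng.choice(
            np.asarray(pool, dtype=object), size=min(extra, len(pool)), replace=False
        )
        chosen.extend(str(c) for c in picks)
    chosen.sort(key=classes.index)
    return chosen


def generate_study(config: StudyConfig) -> tuple[list[SeriesBundle], GroundTruth]:
    """Generate a synthetic multi-series study.

    The generative model for probe ``p`` of gene ``g`` in sample ``s`` of
    series ``b`` is::

        x_gps = mu_g + beta_{g,class(s)} + gamma_{g,b} + o_p + delta_{g,b} * eps

    with ``eps ~ Normal(0, noise_sd)`` and a fixed per-probe offset
    ``o_p ~ Normal(0, 0.25)``.  Series flagged ``linear16`` are emitted as
    ``2**x`` rescaled so their maximum equals 65535.  Deterministic given
    ``config.seed``.

    Returns the list of series bundles and the :class:`GroundTruth` used to
    generate them.
    """
    config.validate()
    study_rng = np.random.default_rng(config.seed)
    classes = list(config.classes)
    n_genes = config.n_genes_global

    genes = [f"G{i:05d}" for i in range(n_genes)]
    perm = study_rng.permutation(n_genes)
    n_core = int(round(config.core_fraction * n_genes))
    core = [genes[i] for i in perm[:n_core]]
    noncore = [genes[i] for i in perm[n_core:]]
    panel_size = int(round(config.panel_fraction * n_genes))

    # baselines: planted genes sit near array background in their "off"
    # classes so a +planted_effect shift lands mid-range, the way real
    # high-fold-change genes behave on microarrays
    planted = sorted(
        study_rng.choice(np.asarray(core, dtype=object), size=config.n_planted_deg, replace=False)
    )
    planted_set = set(str(g) for g in planted)
    mu = pd.Series(
        np.clip(study_rng.normal(8.0, 1.5, size=n_genes), 4.5, 13.0), index=genes
    )
    mu[sorted(planted_set)] = study_rng.normal(5.0, 0.4, size=len(planted_set))

    # each planted gene is near-"off" in some classes and "on" in the rest;
    # every class carries its own small modulation (real genes are rarely at
    # exactly equal levels in two states) and each on-class exceeds every
    # off-class by at least planted_effect
    beta = pd.DataFrame(0.0, index=genes, columns=classes)
    for g in sorted(planted_set):
        n_up = int(study_rng.integers(1, len(classes)))  # proper nonempty subset
        up = set(study_rng.choice(len(classes), size=n_up, replace=False).tolist())
        mod = study_rng.uniform(0.0, config.planted_class_spread, size=len(classes))
        off_max = max(mod[i] for i in range(len(classes)) if i not in up)
        for i, cls in enumerate(classes):
            beta.loc[g, cls] = (
                config.planted_effect + off_max + mod[i] if i in up else mod[i]
            )

    # probe structure is shared across series (one global probe catalogue)
    n_probes = study_rng.integers(
        config.probes_per_gene[0], config.probes_per_gene[1] + 1, size=n_genes
    )
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g, k in zip(genes, n_probes):
        for j in range(int(k)):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_gene.append(g)
    probe_offsets = pd.Series(
        study_rng.normal(0.0, 0.25, size=len(probe_ids)), index=probe_ids
    )
    probe_map_all = dict(zip(probe_ids, probe_gene))

    series_ids = [f"SYN{i + 1:03d}" for i in range(config.n_series)]
    gamma = pd.DataFrame(0.0, index=genes, columns=series_ids)
    delta = pd.DataFrame(1.0, index=genes, columns=series_ids)

    bundles: list[SeriesBundle] = []
    for i, sid in enumerate(series_ids):
        rng = np.random.default_rng(_child_seed(config.seed, i))
        series_class_set = _series_classes(rng, config, i)
        # every 1/fraction-th series is linear; extension-stable and exact
        f = config.linear_scale_fraction
        is_linear = int((i + 1) * f) > int(i * f)
        panel = core + [
            str(g)
            for g in rng.choice(
                np.asarray(noncore, dtype=object),
                size=max(0, panel_size - n_core),
                replace=False,
            )
        ]
        panel = sorted(panel)
        gamma[sid] = rng.normal(0.0, config.batch_sd_add, size=n_genes)
        delta[sid] = np.exp(rng.normal(0.0, config.batch_sd_mult, size=n_genes))

        country = str(rng.choice(np.asarray(config.countries, dtype=object)))
        technology = "I" if i % 4 == 3 else "A"
        platform = f"GPL-{technology}{i + 1:02d}"

        weight = {
            c: w * len(config.class_weights) / sum(config.class_weights)
            for c, w in zip(config.classes, config.class_weights)
        }
        sample_labels: list[str] = []
        for cls in series_class_set:
            base = int(
                rng.integers(
                    config.samples_per_class_per_series[0],
                    config.samples_per_class_per_series[1] + 1,
                )
            )
            n_s = max(2, int(round(base * weight[cls])))
            sample_labels.extend([cls] * n_s)
        sample_ids = [f"{sid}_s{j + 1:03d}" for j in range(len(sample_labels))]
        annotations = [
            SampleAnnotation(
                sample_id=s,
                series_id=sid,
                class_label=c,
                country=country,
                platform=platform,
                technology=technology,
            )
            for s, c in zip(sample_ids, sample_labels)
        ]

        panel_probes = [p for p in probe_ids if probe_map_all[p] in set(panel)]
        gene_of = np.asarray([probe_map_all[p] for p in panel_probes], dtype=object)
        base = (
            mu[gene_of].to_numpy()
            + gamma.loc[gene_of, sid].to_numpy()
            + probe_offsets[panel_probes].to_numpy()
        )
        cls_shift = beta.loc[gene_of, sample_labels].to_numpy()
        eps = rng.normal(0.0, config.noise_sd, size=(len(panel_probes), len(sample_ids)))
        x = base[:, None] + cls_shift + delta.loc[gene_of, sid].to_numpy()[:, None] * eps

        scale = "log2"
        if is_linear:
            v = np.power(2.0, x)
            v *= LINEAR16_MAX / v.max()
            x = np.minimum(v, LINEAR16_MAX)  # guard rounding overshoot
            scale = "linear16"

        bundle = SeriesBundle(
            series_id=sid,
            expression=pd.DataFrame(x, index=panel_probes, columns=sample_ids),
            probe_map={p: probe_map_all[p] for p in panel_probes},
            samples=annotations,
            scale=scale,
        )
        bundle.validate()
        bundles.append(bundle)

    truth = GroundTruth(
        planted_deg_symbols=planted_set,
        class_effects=beta,
        batch_add=gamma,
        batch_mult=delta,
        baseline_means=mu,
    )
    return bundles, truth


# ---------------------------------------------------------------------------
# disk format

_SAMPLE_COLUMNS = [
    "sample_id",
    "series_id",
    "class_label",
    "country",
    "platform",
    "technology",
    "scale",
]


def write_series_bundle(bundle: SeriesBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as ``expression.tsv`` + ``probes.tsv`` + ``samples.tsv``.

    Values are written with six decimal places; refuses bundles violating
    their scale invariants.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    expr_path = directory / "expression.tsv"
    out = bundle.expression.copy()
    out.index.name = "probe_id"
    out.to_csv(expr_path, sep="\t", float_format="%.6f")

    probes_path = directory / "probes.tsv"
    pd.DataFrame(
        {"probe_id": list(bundle.probe_map), "gene_symbol": list(bundle.probe_map.values())}
    ).to_csv(probes_path, sep="\t", index=False)

    samples_path = directory / "samples.tsv"
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "series_id": a.series_id,
                "class_label": a.class_label,
                "country": a.country,
                "platform": a.platform,
                "technology": a.technology,
                "scale": bundle.scale,
            }
            for a in bundle.samples
        ]
    ).to_csv(samples_path, sep="\t", index=False)
    return {"expression": expr_path, "probes": probes_path, "samples": samples_path}


def read_series_bundle(directory: str | Path) -> SeriesBundle:
    """Read a bundle written by :func:`write_series_bundle`.

    Raises :class:`BundleFormatError` naming the offending file (and row,
    for cell-level problems) on any schema violation.
    """
    directory = Path(directory)
    for name in ("expression.tsv", "probes.tsv", "samples.tsv"):
        if not (directory / name).exists():
            raise BundleFormatError(f"missing file: {directory / name}")

    probes = pd.read_csv(directory / "probes.tsv", sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in probes.columns:
            raise BundleFormatError(f"probes.tsv: missing column {col!r}")
    probe_map = dict(zip(probes["probe_id"], probes["gene_symbol"]))

    samples = pd.read_csv(directory / "samples.tsv", sep="\t", dtype=str)
    for col in _SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise BundleFormatError(f"samples.tsv: missing column {col!r}")
    scales = samples["scale"].unique()
    if len(scales) != 1:
        raise BundleFormatError("samples.tsv: inconsistent scale column")
    annotations = [
        SampleAnnotation(
            sample_id=r.sample_id,
            series_id=r.series_id,
            class_label=r.class_label,
            country=r.country,
            platform=r.platform,
            technology=r.technology,
        )
        for r in samples.itertuples()
    ]

    raw = pd.read_csv(directory / "expression.tsv", sep="\t", dtype=str)
    if raw.columns[0] != "probe_id":
        raise BundleFormatError("expression.tsv: first column must be 'probe_id'")
    raw = raw.set_index("probe_id")
    expected = [a.sample_id for a in annotations]
    if list(raw.columns) != expected:
        raise BundleFormatError(
            "expression.tsv: sample columns do not match samples.tsv "
            f"({list(raw.columns)[:3]}... vs {expected[:3]}...)"
        )
    try:
        expr = raw.astype(float)
    except ValueError:
        for probe, row in raw.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise BundleFormatError(
                        f"expression.tsv: non-numeric cell at row {probe!r}, "
                        f"column {col!r}: {cell!r}"
                    ) from None
        raise
    unmapped = [p for p in expr.index if p not in probe_map]
    if unmapped:
        raise BundleFormatError(
            f"expression.tsv: probes absent from probes.tsv: {unmapped[:5]}"
        )

    series_ids = {a.series_id for a in annotations}
    if len(series_ids) != 1:
        raise BundleFormatError("samples.tsv: multiple series_id values in one bundle")
    bundle = SeriesBundle(
        series_id=series_ids.pop(),
        expression=expr,
        probe_map={p: probe_map[p] for p in expr.index},
        samples=annotations,
        scale=str(scales[0]),
    )
    bundle.validate()
    return bundle
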