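import numpy as np
import pandas as pd
import pytest

from dermprof import StudyConfig, generate_study
from dermprof.integrate import summarize_and_merge
from dermprof.synthio import SampleAnnotation, SeriesBundle

#: compact study used by unit tests (full-size studies live in the
#: acceptance suite)
SMALL_STUDY = StudyConfig(
    n_series=5,
    n_genes_global=200,
    n_planted_deg=8,
    samples_per_class_per_series=(3, 5),
    seed=101,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SMALL_STUDY)


@pytest.fixture(scope="session")
def small_bundles(small_study):
    return small_study[0]


@pytest.fixture(scope="session")
def small_truth(small_study):
    return small_study[1]


@pytest.fixture(scope="session")
def merged_mean(small_bundles):
    return summarize_and_merge(small_bundles, "mean")


def make_bundle(
    values: np.ndarray,
    series_id: str = "S1",
    scale: str = "log2",
    class_labels=None,
    genes=None,
) -> SeriesBundle:
    """Hand-built single-probe-per-gene bundle for targeted tests."""
    n_probes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n_probes)]
    probes = [f"{g}_p1" for g in genes]
    sample_ids = [f"{series_id}_s{j:02d}" for j in range(n_samples)]
    if class_labels is None:
        class_labels = ["NSK"] * n_samples
    samples = [
        SampleAnnotation(
            sample_id=s,
            series_id=series_id,
            class_label=c,
            country="USA",
            platform="GPL-T1",
            technology="A",
        )
        for s, c in zip(sample_ids, class_labels)
    ]
    return SeriesBundle(
        series_id=series_id,
        expression=pd.DataFrame(values, index=probes, columns=sample_ids),
        probe_map=dict(zip(probes, genes)),
        samples=samples,
        scale=scale,
    )
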