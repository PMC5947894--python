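"""Published design of the integrated skin-state study this package targets.

Per-series retained-sample and excluded-outlier counts of the 24 public
microarray series (NCBI GEO), and the per-state sample counts of the final
integrated cohort.  These are study-design inputs: the bookkeeping targets
(770 collected arrays, 92 outliers, 678 retained; 160/236/282 and 396/282
samples under the collapsed taxonomies) follow from them by computation.
"""

from __future__ import annotations

import pandas as pd

#: (series id, technology, retained high-quality samples, excluded outliers)
SERIES_MANIFEST: tuple[tuple[str, str, int, int], ...] = (
    ("GSE2503", "Affymetrix", 10, 1),
    ("GSE3189", "Affymetrix", 66, 4),
    ("GSE6710", "Affymetrix", 12, 1),
    ("GSE7553", "Affymetrix", 44, 2),
    ("GSE13355", "Affymetrix", 57, 7),
    ("GSE14905", "Affymetrix", 20, 1),
    ("GSE15605", "Affymetrix", 46, 18),
    ("GSE29359", "Illumina", 75, 7),
    ("GSE30999", "Affymetrix", 74, 11),
    ("GSE32407", "Affymetrix", 10, 0),
    ("GSE32628", "Illumina", 14, 1),
    ("GSE32924", "Affymetrix", 7, 1),
    ("GSE36150", "Affymetrix", 10, 5),
    ("GSE39612", "Affymetrix", 28, 12),
    ("GSE42109", "Affymetrix", 10, 1),
    ("GSE42677", "Affymetrix", 10, 0),
    ("GSE45216", "Affymetrix", 28, 2),
    ("GSE46517", "Affymetrix", 78, 10),
    ("GSE52471", "Affymetrix", 10, 3),
    ("GSE53223", "Affymetrix", 14, 4),
    ("GSE53462", "Illumina", 25, 1),
    ("GSE55664", "Illumina", 10, 0),
    ("GSE66359", "Affymetrix", 8, 0),
    ("GSE82105", "Affymetrix", 12, 0),
)

#: retained samples per skin state in the integrated cohort
CLASS_COUNTS: dict[str, int] = {
    "BCC": 43,
    "SCC": 84,
    "MCC": 33,
    "PRIMEL": 118,
    "METMEL": 118,
    "NSK": 250,
    "NEV": 32,
}


def series_table() -> pd.DataFrame:
    return pd.DataFrame(
        SERIES_MANIFEST,
        columns=["series_id", "technology", "n_retained", "n_outliers"],
    )


def sample_bookkeeping() -> dict[str, int]:
    """Initial / excluded / retained array counts across the 24 series."""
    t = series_table()
    retained = int(t["n_retained"].sum())
    outliers = int(t["n_outliers"].sum())
    return {
        "initial": retained + outliers,
        "outliers": outliers,
        "retained": retained,
    }
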