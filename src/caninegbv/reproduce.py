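"""Reproduction of the published study statistics from its supplementary data.

The study deposited its per-animal data as journal supplementary files:
an Excel table of CHD/CED classes and the 17 marker genotypes (S1), and a
table of the patented marker weights (S3).  Those files are not
redistributable inside this package, so this module only *runs* against
user-supplied copies:

1. obtain the supplementary files from the journal record;
2. place them (or point to them) as ``data/reproduction/s1_cohort.xlsx``
   and ``data/reproduction/s3_weights.tsv`` — the weights file uses the
   panel-file columns ``marker_id, w_hom, w_het``;
3. call :func:`reproduce_study`, which scores the cohort and runs the full
   validation battery, returning the :class:`~caninegbv.ValidationReport`
   whose sections carry the published quantities (GBV(S) range, group
   medians/IQRs, Kruskal-Wallis statistics, logistic ORs and AUCs, stepwise
   models, dominance relative risks).

Column headings in S1 are mapped at ingest via ``column_map`` so the
canonical cohort schema stays fixed whatever the deposited layout.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .cohort_io import Cohort, read_cohort
from .marker_panel import MarkerPanel, bundled_panel
from .validation_pipeline import ValidationConfig, ValidationReport, run_validation

__all__ = [
    "DEFAULT_S1_PATH",
    "DEFAULT_S3_PATH",
    "apply_weights",
    "load_study_cohort",
    "reproduce_study",
]

DEFAULT_S1_PATH = Path("data/reproduction/s1_cohort.xlsx")
DEFAULT_S3_PATH = Path("data/reproduction/s3_weights.tsv")


def apply_weights(panel: MarkerPanel, s3_path: str | Path) -> MarkerPanel:
    """Return a panel with the marker weights replaced from an S3-style file.

    The file is tab-separated with columns ``marker_id, w_hom, w_het``
    (the patent's 'homozygous' and 'heterozygous' weight columns); every
    panel marker must be present.
    """
    s3_path = Path(s3_path)
    if not s3_path.exists():
        raise FileNotFoundError(
            f"weights file {s3_path} not found; supply the supplementary "
            "marker-weight table (not redistributable with this package)"
        )
    df = pd.read_csv(s3_path, sep="\t", comment="#", dtype={"marker_id": str})
    missing = set(panel.marker_ids) - set(df["marker_id"])
    if missing:
        raise ValueError(f"weights file lacks markers: {sorted(missing)}")
    by_id = df.set_index("marker_id")
    markers = tuple(
        replace(
            m,
            w_hom=float(by_id.loc[m.marker_id, "w_hom"]),
            w_het=float(by_id.loc[m.marker_id, "w_het"]),
        )
        for m in panel
    )
    return MarkerPanel(markers)


def load_study_cohort(
    s1_path: str | Path = DEFAULT_S1_PATH,
    s3_path: str | Path = DEFAULT_S3_PATH,
    panel: MarkerPanel | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Load the deposited study cohort against the published panel + weights."""
    s1_path = Path(s1_path)
    if not s1_path.exists():
        raise FileNotFoundError(
            f"study cohort file {s1_path} not found; supply the supplementary "
            "genotype/phenotype table (not redistributable with this package)"
        )
    panel = apply_weights(panel or bundled_panel(), s3_path)
    return read_cohort(s1_path, panel, column_map=column_map)


def reproduce_study(
    s1_path: str | Path = DEFAULT_S1_PATH,
    s3_path: str | Path = DEFAULT_S3_PATH,
    config: ValidationConfig | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ValidationReport:
    """Run the full validation battery on the deposited study data."""
    cohort = load_study_cohort(s1_path, s3_path, column_map=column_map)
    return run_validation(cohort, cohort.panel, config)
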