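"""Genomic breeding value (GBV) computation and cohort standardization.

The patented CHD test scores each animal by summing marker-specific weights
over the 17-marker panel: mutant homozygotes receive the marker's homozygous
weight ``w_hom``, heterozygotes its heterozygous weight ``w_het``, and
wild-type homozygotes the *negative* of ``w_hom``.  The sum is the animal's
GBV.  Standardization to GBV(S) subtracts the cohort-wide mean and divides
by the cohort-wide range, so a symmetric GBV distribution spans exactly
[-0.5, +0.5]; skew shifts the end points (the study observed -0.613 to
+0.387) while preserving rank order.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import Cohort, dosage_matrix
from .marker_panel import MarkerDefinition, MarkerPanel

__all__ = [
    "GbvError",
    "marker_score",
    "compute_gbv",
    "standardize_gbv",
    "score_cohort",
]

_POLICIES = ("exclude", "zero")


class GbvError(ValueError):
    """Invalid input to GBV computation."""


def marker_score(dosage: object, marker: MarkerDefinition) -> float | None:
    """Weight contributed by one marker genotype.

    dosage 2 -> +w_hom, dosage 1 -> w_het, dosage 0 -> -w_hom; missing -> None.
    """
    if dosage is None or pd.isna(dosage):
        return None
    dosage = int(dosage)
    if dosage == 0:
        return -marker.w_hom
    if dosage == 1:
        return marker.w_het
    if dosage == 2:
        return marker.w_hom
    raise GbvError(f"dosage {dosage} not in {{0,1,2}}")


def compute_gbv(
    dosages: pd.DataFrame,
    panel: MarkerPanel,
    missing_policy: str = "exclude",
) -> pd.DataFrame:
    """Per-animal GBV from an animals x markers dosage matrix.

    Under ``missing_policy="exclude"`` (default) any missing marker leaves the
    animal's GBV undefined (NaN); under ``"zero"`` missing markers contribute
    nothing and ``n_missing_markers`` records how many were imputed away.

    Returns a DataFrame indexed like ``dosages`` with columns ``gbv`` (float)
    and ``n_missing_markers`` (int).
    """
    if missing_policy not in _POLICIES:
        raise GbvError(f"unknown missing_policy {missing_policy!r}")
    unknown = set(dosages.columns) - set(panel.marker_ids)
    if unknown:
        raise GbvError(f"dosage columns not in panel: {sorted(unknown)}")
    d = dosages.to_numpy(dtype=float, na_value=np.nan)
    w_hom = np.array([panel[m].w_hom for m in dosages.columns])
    w_het = np.array([panel[m].w_het for m in dosages.columns])
    scores = np.where(d == 0, -w_hom, np.where(d == 1, w_het, w_hom))
    scores = np.where(np.isnan(d), np.nan, scores)
    n_missing = np.isnan(d).sum(axis=1)
    if missing_policy == "exclude":
        gbv = scores.sum(axis=1)  # any NaN propagates
    else:
        gbv = np.nansum(scores, axis=1)
    return pd.DataFrame(
        {"gbv": gbv, "n_missing_markers": n_missing.astype(int)},
        index=dosages.index,
    )


def standardize_gbv(gbvs: pd.Series | np.ndarray) -> tuple[pd.Series, dict[str, float]]:
    """Standardize GBVs to GBV(S): subtract the cohort mean, divide by the range.

    NaN entries (animals excluded under the missing policy) stay NaN and do not
    enter the standardization constants.  Returns ``(gbv_s, constants)`` where
    constants records mean/min/max/range so the transform is reproducible.
    Raises :class:`GbvError` when fewer than two distinct finite values exist
    (zero range).
    """
    s = pd.Series(gbvs, dtype=float, copy=True)
    finite = s.dropna()
    if finite.nunique() < 2:
        raise GbvError(
            "standardization needs >= 2 distinct GBV values (zero range)"
        )
    mean, lo, hi = float(finite.mean()), float(finite.min()), float(finite.max())
    constants = {"mean": mean, "min": lo, "max": hi, "range": hi - lo}
    return (s - mean) / (hi - lo), constants


def score_cohort(
    cohort: Cohort,
    panel: MarkerPanel | None = None,
    missing_policy: str = "exclude",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """GBV and GBV(S) for every animal in a cohort.

    Convenience wrapper: dosage encoding, weight summation, standardization.
    Returns a DataFrame with columns ``gbv``, ``gbv_s``, ``n_missing_markers``
    plus the standardization constants.
    """
    panel = panel or cohort.panel
    result = compute_gbv(dosage_matrix(cohort, panel), panel, missing_policy)
    result["gbv_s"], constants = standardize_gbv(result["gbv"])
    return result[["gbv", "gbv_s", "n_missing_markers"]], constants
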