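"""Scalar spectral biomarkers: integrated band areas and intensity ratios.

Each subject's spectrum yields four integrated band intensities (trapezoid
integral of the baseline-corrected band, in absorbance·cm⁻¹) plus two
derived ratios:

* LPR, the lipid-to-protein ratio = area(2800–3000) / area(1470–1700);
* LNR, the lipid-to-nucleic-acid ratio = area(2800–3000) / area(1000–1200).

Areas are computed on baseline-corrected but *not* per-band re-normalized
spectra (re-normalizing each band to unit area would erase the very
quantity being measured); any cross-subject scaling should happen in the
upstream full-spectrum stage.  Negative corrected absorbance is integrated
as-is by default, because clipping would bias weak bands upward;
``clip_negative=True`` is available for sensitivity analysis.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import BandDefinition, CANONICAL_BANDS, band_slice, subtract_linear_baseline
from .spectra_io import SpectralDataset, Spectrum

__all__ = [
    "band_area",
    "band_column",
    "build_feature_table",
    "DEFAULT_FEATURE_BANDS",
    "LPR_NUM",
    "LPR_DEN",
    "LNR_DEN",
]

#: Bands whose integrals populate the feature table, in reporting order.
DEFAULT_FEATURE_BANDS: tuple[BandDefinition, ...] = (
    CANONICAL_BANDS["amide"],
    CANONICAL_BANDS["carb_nucleic"],
    CANONICAL_BANDS["ch_stretch"],
    CANONICAL_BANDS["ester_co"],
)

LPR_NUM = "area_2800_3000"  # lipid CH stretch
LPR_DEN = "area_1470_1700"  # protein amide I+II
LNR_DEN = "area_1000_1200"  # carbohydrates / nucleic acids


def band_column(window: BandDefinition) -> str:
    """Feature-table column name for a band, e.g. ``area_1470_1700``."""
    return f"area_{window.lo:g}_{window.hi:g}".replace(".", "p")


def band_area(
    spectrum: Spectrum,
    window: BandDefinition,
    correct_baseline: bool = True,
    anchor_k: int = 1,
    clip_negative: bool = False,
) -> float:
    """Trapezoid integral of the (baseline-corrected) band, absorbance·cm⁻¹.

    Set ``correct_baseline=False`` if the spectrum was already corrected
    within this window, to avoid applying the correction twice.
    """
    if correct_baseline:
        band = subtract_linear_baseline(spectrum, window, anchor_k=anchor_k)
    else:
        band = band_slice(spectrum, window)
    ab = band.absorbance
    if clip_negative:
        ab = np.clip(ab, 0.0, None)
    return float(np.trapezoid(ab, band.wavenumbers))


def build_feature_table(
    dataset: SpectralDataset,
    bands: Sequence[BandDefinition] = DEFAULT_FEATURE_BANDS,
    column_names: Mapping[str, str] | None = None,
    anchor_k: int = 1,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """One row per subject with band areas and the LPR / LNR ratios.

    Ratio columns are NaN wherever the denominator area is zero.  Column
    names default to ``area_<lo>_<hi>``; ``column_names`` may remap band
    names to custom columns.
    """
    rows = []
    for s in dataset:
        row: dict[str, object] = {"subject_id": s.subject_id, "group": s.group}
        for w in bands:
            col = (column_names or {}).get(w.name, band_column(w))
            row[col] = band_area(
                s, w, anchor_k=anchor_k, clip_negative=clip_negative
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    def safe_ratio(num: str, den: str) -> pd.Series:
        d = table[den]
        return table[num] / d.where(d != 0, np.nan)

    if LPR_NUM in table and LPR_DEN in table:
        table["lpr"] = safe_ratio(LPR_NUM, LPR_DEN)
    if LPR_NUM in table and LNR_DEN in table:
        table["lnr"] = safe_ratio(LPR_NUM, LNR_DEN)
    return table
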