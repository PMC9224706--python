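"""Baseline subtraction and normalization of absorbance spectra.

The analysis chain applies these at two scopes:

* full-spectrum: one linear baseline over the working range followed by
  area normalization, which puts subjects on a common absorbance scale;
* per-band: inside each diagnostic window the baseline is re-fit and the
  band is (optionally) re-normalized to unit area before any shape
  analysis, so only the line shape within the window carries information.

Windows are closed intervals: a grid point belongs to ``[lo, hi]`` iff
``lo <= ν <= hi``.  The four canonical mid-IR diagnostic windows are the
carbohydrate/nucleic-acid band (1000–1200 cm⁻¹), the protein amide I+II
band (1470–1700 cm⁻¹), the lipid-ester C=O band (1720–1760 cm⁻¹) and the
lipid CH-stretching band (2800–3000 cm⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .spectra_io import Spectrum, SpectralDataset

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "FULL_RANGE",
    "band_slice",
    "subtract_linear_baseline",
    "normalize",
    "preprocess_band",
    "preprocess_full",
    "GroupMeanSpectrum",
    "group_mean_spectrum",
]

NormMethod = Literal["area", "vector", "max"]


@dataclass(frozen=True)
class BandDefinition:
    """A named closed wavenumber window ``[lo, hi]`` in cm⁻¹."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


#: Diagnostic windows used throughout the analysis.  ``ester_co_narrow`` is an
#: alternative convention for the C=O band occasionally used for display; all
#: quantitative defaults use ``ester_co`` (1720–1760).
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "carb_nucleic": BandDefinition("carb_nucleic", 1000.0, 1200.0),
    "amide": BandDefinition("amide", 1470.0, 1700.0),
    "ester_co": BandDefinition("ester_co", 1720.0, 1760.0),
    "ester_co_narrow": BandDefinition("ester_co_narrow", 1720.0, 1740.0),
    "ch_stretch": BandDefinition("ch_stretch", 2800.0, 3000.0),
}

#: Working range for full-spectrum normalization, clear of the noisy band edges.
FULL_RANGE = BandDefinition("full", 900.0, 3050.0)


def band_slice(spectrum: Spectrum, window: BandDefinition) -> Spectrum:
    """Restrict a spectrum to the closed window, keeping metadata."""
    mask = window.contains(spectrum.wavenumbers)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"window {window.name!r} [{window.lo}, {window.hi}] lies outside the grid "
            f"[{spectrum.wavenumbers[0]:g}, {spectrum.wavenumbers[-1]:g}]"
        )
    return Spectrum(
        spectrum.wavenumbers[mask],
        spectrum.absorbance[mask],
        subject_id=spectrum.subject_id,
        group=spectrum.group,
    )


def subtract_linear_baseline(
    spectrum: Spectrum, window: BandDefinition, anchor_k: int = 1
) -> Spectrum:
    """Remove the straight line through the window's edge anchors.

    The spectrum is restricted to ``[lo, hi]`` and the line through the two
    anchor points is subtracted.  With ``anchor_k=1`` (default) the anchors
    are the absorbance values at the grid points nearest ``lo`` and ``hi``
    and the corrected absorbance is exactly zero there.  ``anchor_k>1``
    averages the k edge-most points of the window on each side (anchor
    placed at their mean wavenumber), trading exact edge zeros for noise
    robustness; the operation remains idempotent either way.
    """
    band = band_slice(spectrum, window)
    if len(band) < 3:
        raise ValueError(
            f"window {window.name!r} holds only {len(band)} grid points; need >= 3"
        )
    if anchor_k < 1 or 2 * anchor_k > len(band):
        raise ValueError(f"anchor_k={anchor_k} invalid for a {len(band)}-point window")
    wn, ab = band.wavenumbers, band.absorbance
    x0, y0 = wn[:anchor_k].mean(), ab[:anchor_k].mean()
    x1, y1 = wn[-anchor_k:].mean(), ab[-anchor_k:].mean()
    baseline = y0 + (y1 - y0) * (wn - x0) / (x1 - x0)
    return band.with_absorbance(ab - baseline)


def normalize(spectrum: Spectrum, method: NormMethod = "area") -> Spectrum:
    """Scale a spectrum to unit size under the chosen norm.

    ``area``: trapezoidal integral of |A| over the grid equals 1;
    ``vector``: Σ A² = 1; ``max``: max A = 1.
    """
    ab = spectrum.absorbance
    if method == "area":
        norm = float(np.trapezoid(np.abs(ab), spectrum.wavenumbers))
    elif method == "vector":
        norm = float(np.sqrt(np.sum(ab**2)))
    elif method == "max":
        norm = float(np.max(ab)) if ab.size else 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError(
            f"cannot {method}-normalize spectrum {spectrum.subject_id!r}: norm {norm:g}"
        )
    return spectrum.with_absorbance(ab / norm)


def preprocess_band(
    dataset: SpectralDataset,
    window: BandDefinition,
    normalize_after: bool = True,
    anchor_k: int = 1,
    norm_method: NormMethod = "area",
) -> SpectralDataset:
    """Baseline-correct every spectrum within ``window``; optionally re-normalize.

    The output dataset lives on the window grid.  ``normalize_after=True``
    (the default for shape analysis) rescales each corrected band to unit
    area so that only shape differences remain; leave it off when the band
    integral itself is the quantity of interest.
    """

    def one(s: Spectrum) -> Spectrum:
        out = subtract_linear_baseline(s, window, anchor_k=anchor_k)
        if normalize_after:
            out = normalize(out, norm_method)
        return out

    return dataset.map_absorbance(one)


def preprocess_full(
    dataset: SpectralDataset,
    working_range: BandDefinition = FULL_RANGE,
    norm_method: NormMethod = "area",
    anchor_k: int = 1,
) -> SpectralDataset:
    """Full-spectrum stage: one linear baseline over ``working_range``, then
    normalization (area by default), applied to every subject."""

    def one(s: Spectrum) -> Spectrum:
        return normalize(
            subtract_linear_baseline(s, working_range, anchor_k=anchor_k), norm_method
        )

    return dataset.map_absorbance(one)


@dataclass(frozen=True)
class GroupMeanSpectrum:
    """Pointwise group mean with a two-sided confidence band (mean ± t·SEM)."""

    wavenumbers: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    group: str
    n: int
    confidence: float


def group_mean_spectrum(
    dataset: SpectralDataset, group: str, confidence: float = 0.95
) -> GroupMeanSpectrum:
    """Average the spectra of one group with a pointwise t confidence band."""
    sub = dataset.select_group(group)
    n = len(sub)
    if n < 2:
        raise ValueError(f"group {group!r} has {n} subject(s); need >= 2 for a CI")
    mat = sub.to_matrix()
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    return GroupMeanSpectrum(
        wavenumbers=sub.wavenumbers,
        mean=mean,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        group=group,
        n=n,
        confidence=confidence,
    )
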