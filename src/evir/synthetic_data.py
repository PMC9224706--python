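"""Synthetic spectral and feature cohorts with the study's statistical structure.

Two generators are provided so that every pipeline stage is testable
without patient data:

* a *feature-level* generator drawing per-subject scalar markers from
  independent Gaussians whose group means/SDs default to the published
  cohort summary (19 controls / 20 cases; four band areas, three LD1 shape
  scores, plus AFP and PIVKA-II analogues);
* a *spectral* generator composing each subject's absorbance spectrum on
  the instrument grid (650–4000 cm⁻¹, 2 cm⁻¹ step) from Gaussian peaks
  with per-band subject-to-subject amplitude variation, per-peak center
  jitter, a random linear baseline drift, and white measurement noise.
  Case-group effects enter as multiplicative amplitude ratios and/or
  center shifts on selected peaks.

Peak amplitudes are calibrated analytically (a Gaussian peak of amplitude
a and width σ integrates to a·σ·√(2π)) so the four extracted band areas
sit at the control-group target means; case/control amplitude ratios equal
the corresponding target mean ratios.  Markers are generated independently
— between-marker correlations of real cohorts are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, SpectralDataset

__all__ = [
    "PeakSpec",
    "CohortSpec",
    "FeatureCohortSpec",
    "PUBLISHED_FEATURES",
    "SPECTRAL_MARKERS",
    "default_peaks",
    "default_cohort_spec",
    "null_cohort_spec",
    "planted_cohort_spec",
    "group_scale_for_effect",
    "generate_spectrum",
    "generate_cohort",
    "generate_feature_cohort",
    "binormal_auc",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: Published per-marker group parameters: (mean_control, sd_control, mean_case, sd_case).
PUBLISHED_FEATURES: dict[str, tuple[float, float, float, float]] = {
    "area_1470_1700": (12.0, 3.1, 9.7, 3.6),
    "area_1000_1200": (4.16, 1.22, 3.32, 0.99),
    "area_2800_3000": (0.023, 0.006, 0.030, 0.008),
    "area_1720_1760": (0.0012, 0.0007, 0.0017, 0.0008),
    "ld1_1470_1700": (-0.54, 0.77, 0.52, 1.18),
    "ld1_2800_3000": (-0.48, 1.24, 0.46, 0.70),
    "ld1_1720_1760": (-0.77, 1.10, 0.73, 0.90),
    "pivka_ii": (14.0, 4.0, 3205.0, 9987.0),
    "afp": (2.0, 1.0, 193.0, 417.0),
}

#: The seven spectral markers (areas + LD1 shape scores), reporting order.
SPECTRAL_MARKERS: tuple[str, ...] = tuple(k for k in PUBLISHED_FEATURES if k.startswith(("area_", "ld1_")))


def binormal_auc(mean0: float, sd0: float, mean1: float, sd1: float) -> float:
    """AUC of a Gaussian marker: Φ(|Δμ| / √(σ₀² + σ₁²))."""
    from scipy.stats import norm

    return float(norm.cdf(abs(mean1 - mean0) / np.hypot(sd0, sd1)))


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian component of the synthetic spectrum.

    ``group_scale`` multiplies the amplitude and ``group_shift`` (cm⁻¹)
    displaces the center in the case group only.  ``band`` names the
    diagnostic band whose per-subject amplitude factor this peak shares.
    """

    center: float
    amplitude: float
    width: float
    band: str = ""
    group_scale: float = 1.0
    group_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")


def _peak_set(area_targets: Mapping[str, float]) -> tuple[PeakSpec, ...]:
    """Gaussian peaks whose per-band summed areas hit ``area_targets``."""

    def amp(total_area: float, fraction: float, width: float) -> float:
        return total_area * fraction / (width * SQRT_2PI)

    amide, carb, ch, ester = (
        area_targets["amide"],
        area_targets["carb_nucleic"],
        area_targets["ch_stretch"],
        area_targets["ester_co"],
    )
    return (
        # carbohydrate / nucleic-acid band, 1000–1200 cm⁻¹
        PeakSpec(1045.0, amp(carb, 0.43, 15.0), 15.0, band="carb_nucleic"),
        PeakSpec(1080.0, amp(carb, 0.36, 15.0), 15.0, band="carb_nucleic"),
        PeakSpec(1160.0, amp(carb, 0.21, 15.0), 15.0, band="carb_nucleic"),
        # protein amide II and I, 1470–1700 cm⁻¹
        PeakSpec(1545.0, amp(amide, 1 / 3, 13.0), 13.0, band="amide"),
        PeakSpec(1652.0, amp(amide, 2 / 3, 13.0), 13.0, band="amide"),
        # lipid-ester C=O, 1720–1760 cm⁻¹
        PeakSpec(1735.0, amp(ester, 1.0, 6.0), 6.0, band="ester_co"),
        # lipid CH₂ / CH₃ stretches, 2800–3000 cm⁻¹
        PeakSpec(2852.0, amp(ch, 0.30, 8.0), 8.0, band="ch_stretch"),
        PeakSpec(2922.0, amp(ch, 0.48, 10.0), 10.0, band="ch_stretch"),
        PeakSpec(2960.0, amp(ch, 0.22, 9.0), 9.0, band="ch_stretch"),
    )


def _calibrated_peak_set(
    area_targets: Mapping[str, float], n_iter: int = 3
) -> tuple[PeakSpec, ...]:
    """Peaks whose *extracted* band areas (after in-window linear baseline
    correction on the default grid) hit ``area_targets``.

    The analytic a·σ·√(2π) calibration overshoots slightly because the
    closed windows truncate Gaussian tails and the baseline chord removes
    part of each band; a few fixed-point iterations against the actual
    extraction correct for this.
    """
    from .band_features import band_area
    from .preprocess import CANONICAL_BANDS

    peaks = list(_peak_set(dict(area_targets)))
    grid = 650.0 + 2.0 * np.arange(1676)  # default instrument grid
    for _ in range(n_iter):
        absorbance = np.zeros_like(grid)
        for p in peaks:
            absorbance += p.amplitude * np.exp(-0.5 * ((grid - p.center) / p.width) ** 2)
        noiseless = Spectrum(grid, absorbance)
        scale: dict[str, float] = {}
        for band, target in area_targets.items():
            actual = band_area(noiseless, CANONICAL_BANDS[band])
            if actual > 0:
                scale[band] = target / actual
        peaks = [replace(p, amplitude=p.amplitude * scale.get(p.band, 1.0)) for p in peaks]
    return tuple(peaks)


#: Control-group band-area targets (absorbance·cm⁻¹) used for calibration.
_CONTROL_AREAS = {
    "amide": PUBLISHED_FEATURES["area_1470_1700"][0],
    "carb_nucleic": PUBLISHED_FEATURES["area_1000_1200"][0],
    "ch_stretch": PUBLISHED_FEATURES["area_2800_3000"][0],
    "ester_co": PUBLISHED_FEATURES["area_1720_1760"][0],
}

#: Case/control band-area mean ratios.
_CASE_RATIOS = {
    "amide": PUBLISHED_FEATURES["area_1470_1700"][2] / PUBLISHED_FEATURES["area_1470_1700"][0],
    "carb_nucleic": PUBLISHED_FEATURES["area_1000_1200"][2] / PUBLISHED_FEATURES["area_1000_1200"][0],
    "ch_stretch": PUBLISHED_FEATURES["area_2800_3000"][2] / PUBLISHED_FEATURES["area_2800_3000"][0],
    "ester_co": PUBLISHED_FEATURES["area_1720_1760"][2] / PUBLISHED_FEATURES["area_1720_1760"][0],
}

#: Case-group center shifts (cm⁻¹) planting the band-shape differences
#: observed for the amide, CH-stretch and ester bands (none for the
#: carbohydrate/nucleic-acid band, whose shape did not differ).
_CASE_SHIFTS = {1652.0: 3.0, 2922.0: 1.5, 1735.0: 2.0}


_DEFAULT_PEAK_CACHE: dict[bool, tuple[PeakSpec, ...]] = {}


def default_peaks(
    planted: bool = True, area_targets: Mapping[str, float] | None = None
) -> tuple[PeakSpec, ...]:
    """Default peak list; ``planted=True`` applies the case-group effects."""
    if area_targets is None and planted in _DEFAULT_PEAK_CACHE:
        return _DEFAULT_PEAK_CACHE[planted]
    peaks = _calibrated_peak_set(dict(area_targets or _CONTROL_AREAS))
    if planted:
        peaks = tuple(
            replace(
                p,
                group_scale=_CASE_RATIOS.get(p.band, 1.0),
                group_shift=_CASE_SHIFTS.get(p.center, 0.0),
            )
            for p in peaks
        )
    if area_targets is None:
        _DEFAULT_PEAK_CACHE[planted] = peaks
    return peaks


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic spectral cohort.

    Defaults are the study conditions: 19 controls and 20 cases on the
    650–4000 cm⁻¹ grid at 2 cm⁻¹ (1676 points).  ``amplitude_cv`` is the
    per-band between-subject coefficient of variation (lognormal, mean 1),
    the dominant source of subject-level variance; ``center_jitter_sd``
    perturbs each peak center per subject (cm⁻¹); ``noise_sd`` is additive
    white Gaussian measurement noise on absorbance, small relative to the
    weakest band; ``drift_slope_range`` bounds a random linear baseline.
    """

    n_control: int = 19
    n_case: int = 20
    peaks: tuple[PeakSpec, ...] = field(default_factory=default_peaks)
    noise_sd: float = 1e-6
    drift_slope_range: tuple[float, float] = (-1e-6, 1e-6)
    amplitude_cv: float = 0.25
    center_jitter_sd: float = 1.0
    wn_min: float = 650.0
    wn_max: float = 4000.0
    wn_step: float = 2.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one subject per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if not self.wn_min < self.wn_max:
            raise ValueError("wn_min must be < wn_max")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.wn_max - self.wn_min) / self.wn_step)) + 1
        return self.wn_min + self.wn_step * np.arange(n)


def default_cohort_spec(seed: int | None = 0, **overrides) -> CohortSpec:
    """Study-condition cohort with the published group effects planted."""
    return CohortSpec(peaks=default_peaks(planted=True), seed=seed, **overrides)


def null_cohort_spec(seed: int | None = 0, **overrides) -> CohortSpec:
    """Cohort with *no* group effects: both groups share every parameter."""
    return CohortSpec(peaks=default_peaks(planted=False), seed=seed, **overrides)


def group_scale_for_effect(d: float, cv: float) -> float:
    """Amplitude ratio s giving standardized band-area effect size d.

    With multiplicative subject variation of coefficient of variation
    ``cv``, a case/control amplitude ratio s yields
    d = (s−1) / (cv·√((1+s²)/2)); this inverts that relation (s ≥ 1).
    """
    c = (d * cv) ** 2 / 2.0
    if c >= 1.0:
        raise ValueError(f"effect d={d} unreachable at cv={cv}")
    return float((1.0 + np.sqrt(c * (2.0 - c))) / (1.0 - c))


def planted_cohort_spec(
    effect_d: float,
    bands: Sequence[str] = ("ch_stretch",),
    shift_bands: Mapping[float, float] | None = None,
    seed: int | None = 0,
    **overrides,
) -> CohortSpec:
    """Cohort with a controlled planted effect of standardized size ``effect_d``.

    Amplitude ratios on ``bands`` are set from ``effect_d`` via
    :func:`group_scale_for_effect`; ``shift_bands`` maps peak centers to
    case-group shifts (cm⁻¹) for planting shape effects.
    """
    cv = overrides.get("amplitude_cv", 0.25)
    scale = group_scale_for_effect(effect_d, cv)
    shift_bands = dict(shift_bands or {})
    peaks = tuple(
        replace(
            p,
            group_scale=scale if p.band in bands else 1.0,
            group_shift=shift_bands.get(p.center, 0.0),
        )
        for p in default_peaks(planted=False)
    )
    return CohortSpec(peaks=peaks, seed=seed, **overrides)


def generate_spectrum(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> Spectrum:
    """Draw one subject's spectrum: Σ Gaussian peaks + linear drift + noise."""
    if group not in ("control", "case"):
        raise ValueError(f"group must be 'control' or 'case', got {group!r}")
    grid = spec.grid
    is_case = group == "case"
    band_names = sorted({p.band for p in spec.peaks})
    sigma_ln = float(np.sqrt(np.log1p(spec.amplitude_cv**2)))
    band_factor = {
        b: float(np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))) for b in band_names
    }
    absorbance = np.zeros_like(grid)
    for p in spec.peaks:
        center = p.center + (p.group_shift if is_case else 0.0)
        center += rng.normal(0.0, spec.center_jitter_sd)
        amp = p.amplitude * band_factor.get(p.band, 1.0)
        if is_case:
            amp *= p.group_scale
        absorbance += amp * np.exp(-0.5 * ((grid - center) / p.width) ** 2)
    slope = rng.uniform(*spec.drift_slope_range)
    absorbance += slope * (grid - grid[0])
    if spec.noise_sd > 0:
        absorbance += rng.normal(0.0, spec.noise_sd, size=grid.size)
    return Spectrum(grid, absorbance, subject_id=subject_id, group=group)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> SpectralDataset:
    """Labelled cohort of ``n_control + n_case`` spectra; deterministic given seed."""
    rng = rng or np.random.default_rng(spec.seed)
    spectra = [
        generate_spectrum(spec, "control", rng, subject_id=f"ctrl_{i + 1:02d}")
        for i in range(spec.n_control)
    ] + [
        generate_spectrum(spec, "case", rng, subject_id=f"case_{i + 1:02d}")
        for i in range(spec.n_case)
    ]
    return SpectralDataset(spectra)


@dataclass(frozen=True)
class FeatureCohortSpec:
    """Parameters of a synthetic feature-level cohort.

    ``markers`` maps marker name → (mean_control, sd_control, mean_case,
    sd_case); defaults to the published summary for the seven spectral
    markers plus the AFP / PIVKA-II analogues.  Draws are independent
    Gaussians (real between-marker correlations are not modelled, and the
    heavy-tailed clinical markers are only caricatured by a Gaussian).
    """

    markers: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(PUBLISHED_FEATURES)
    )
    n_control: int = 19
    n_case: int = 20
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one subject per group")
        for name, (_, sd0, _, sd1) in self.markers.items():
            if sd0 <= 0 or sd1 <= 0:
                raise ValueError(f"marker {name!r}: SDs must be > 0")


def generate_feature_cohort(
    spec: FeatureCohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Feature table of independent Gaussian marker draws, one row per subject."""
    rng = rng or np.random.default_rng(spec.seed)
    n0, n1 = spec.n_control, spec.n_case
    table = pd.DataFrame(
        {
            "subject_id": [f"ctrl_{i + 1:02d}" for i in range(n0)]
            + [f"case_{i + 1:02d}" for i in range(n1)],
            "group": ["control"] * n0 + ["case"] * n1,
        }
    )
    for name, (m0, s0, m1, s1) in spec.markers.items():
        table[name] = np.concatenate(
            [rng.normal(m0, s0, size=n0), rng.normal(m1, s1, size=n1)]
        )
    return table
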