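"""Reading, writing and aligning mid-IR absorbance spectra.

The canonical in-memory objects are :class:`Spectrum` (one subject's
absorbance versus wavenumber) and :class:`SpectralDataset` (a labelled
cohort of spectra sharing one wavenumber grid).  The spectral axis is
always stored ascending in cm⁻¹; files stored descending (the common
instrument-export convention, 4000 → 650 cm⁻¹) are reversed on ingestion.

Supported formats:

``csv_wide``
    First column ``wavenumber``, one numeric column per subject.  Group
    labels live in a separate two-column manifest CSV
    (``subject_id,group``) so the spectral file stays numeric-only.
``csv_long``
    Tidy rows ``subject_id,wavenumber,absorbance`` with an optional
    ``group`` column.
``jcampdx``
    Read-only minimal JCAMP-DX dialect: ``##XYDATA=(X++(Y..Y))`` with
    ``##FIRSTX``/``##DELTAX``/``##YFACTOR`` headers, one spectrum per file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "MarkerTable",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "read_jcampdx",
    "common_grid",
    "average_replicates",
]

GROUPS = ("control", "case")
Format = Literal["csv_wide", "csv_long", "jcampdx"]


class SpectraFormatError(ValueError):
    """A spectral file violates the declared format."""


@dataclass(frozen=True)
class Spectrum:
    """Absorbance of one subject on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray
        Spectral axis in cm⁻¹, strictly increasing.
    absorbance : ndarray
        Unitless absorbance, same length as ``wavenumbers``, all finite.
    subject_id : str
        Subject identifier.
    group : str
        ``"control"``, ``"case"`` or ``"unknown"``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    subject_id: str = "anonymous"
    group: str = "unknown"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise ValueError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbance values"
            )
        if wn.size and np.any(np.diff(wn) <= 0):
            # tolerate descending storage by flipping to the canonical order
            if np.all(np.diff(wn) < 0):
                wn, ab = wn[::-1], ab[::-1]
            else:
                bad = wn[np.flatnonzero(np.diff(wn) <= 0)[0]]
                raise SpectraFormatError(
                    f"wavenumber axis not strictly monotonic near {bad:g} cm^-1"
                )
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"non-finite absorbance in spectrum {self.subject_id!r}")
        if self.group not in GROUPS and self.group != "unknown":
            raise ValueError(f"unknown group label {self.group!r}")
        wn.flags.writeable = False
        ab.flags.writeable = False
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, values: np.ndarray) -> "Spectrum":
        return replace(self, absorbance=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class SpectralDataset:
    """A cohort of spectra on one shared wavenumber grid."""

    spectra: tuple[Spectrum, ...]

    def __init__(self, spectra: Iterable[Spectrum]):
        spectra = tuple(spectra)
        if not spectra:
            raise ValueError("dataset must contain at least one spectrum")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(
                s.wavenumbers, grid
            ):
                raise ValueError(
                    f"spectrum {s.subject_id!r} is not on the shared wavenumber grid; "
                    "call common_grid() first"
                )
        object.__setattr__(self, "spectra", spectra)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.spectra]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.spectra]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 0 = control, 1 = case. Raises if any group unknown."""
        if any(g == "unknown" for g in self.groups):
            missing = [s.subject_id for s in self.spectra if s.group == "unknown"]
            raise ValueError(f"group labels missing for subjects {missing}")
        return np.array([1 if g == "case" else 0 for g in self.groups], dtype=int)

    def to_matrix(self) -> np.ndarray:
        """Stack absorbances into a (subjects × wavenumbers) matrix."""
        return np.vstack([s.absorbance for s in self.spectra])

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        return SpectralDataset(self.spectra[i] for i in indices)

    def select_group(self, group: str) -> "SpectralDataset":
        kept = [s for s in self.spectra if s.group == group]
        if not kept:
            raise ValueError(f"no spectra in group {group!r}")
        return SpectralDataset(kept)

    def map_absorbance(self, fn) -> "SpectralDataset":
        return SpectralDataset(fn(s) for s in self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


@dataclass
class MarkerTable:
    """Per-subject scalar markers (e.g. AFP in ng/mL, PIVKA-II in mAU/mL).

    Thin wrapper around a tidy DataFrame with one row per subject, a
    ``subject_id`` column, a ``group`` column and one numeric column per
    marker.  Marker names must be unique.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"marker table needs a {col!r} column")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if df.columns.duplicated().any():
            raise ValueError("marker names must be unique")
        self.data = df.reset_index(drop=True)

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "group")]

    @classmethod
    def read_csv(cls, path: str | Path) -> "MarkerTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers / writers


def _check_duplicate_wavenumbers(wn: np.ndarray) -> None:
    uniq, counts = np.unique(wn, return_counts=True)
    if np.any(counts > 1):
        raise SpectraFormatError(
            f"duplicated wavenumber {uniq[counts > 1][0]:g} cm^-1 in input file"
        )


def _load_manifest(manifest: str | Path | None) -> dict[str, str]:
    if manifest is None:
        return {}
    df = pd.read_csv(manifest)
    if not {"subject_id", "group"} <= set(df.columns):
        raise SpectraFormatError(
            "label manifest must have columns subject_id,group"
        )
    return dict(zip(df["subject_id"].astype(str), df["group"].astype(str)))


def read_spectra(
    path: str | Path,
    format: Format = "csv_wide",
    manifest: str | Path | None = None,
) -> SpectralDataset:
    """Read a cohort of spectra from ``path`` in the declared ``format``.

    Group labels are attached from ``manifest`` (two-column CSV
    ``subject_id,group``) or, for ``csv_long``, from an in-file ``group``
    column; subjects without a label get group ``"unknown"`` and group-wise
    operations downstream will refuse them.
    """
    path = Path(path)
    labels = _load_manifest(manifest)
    if format == "csv_wide":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise SpectraFormatError("wide CSV needs a wavenumber column plus subjects")
        wn = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
        _check_duplicate_wavenumbers(wn)
        if df.isna().any().any():
            raise SpectraFormatError("ragged columns: missing values in wide CSV")
        spectra = [
            Spectrum(wn, df[col].to_numpy(dtype=float), subject_id=str(col),
                     group=labels.get(str(col), "unknown"))
            for col in df.columns[1:]
        ]
        return SpectralDataset(spectra)
    if format == "csv_long":
        df = pd.read_csv(path)
        required = {"subject_id", "wavenumber", "absorbance"}
        if not required <= set(df.columns):
            raise SpectraFormatError(
                f"long CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        spectra = []
        for sid, sub in df.groupby("subject_id", sort=False):  # keep file order
            wn = sub["wavenumber"].to_numpy(dtype=float)
            _check_duplicate_wavenumbers(wn)
            group = labels.get(str(sid), "unknown")
            if "group" in sub.columns and group == "unknown":
                g = sub["group"].dropna().unique()
                if g.size == 1:
                    group = str(g[0])
            order = np.argsort(wn)
            spectra.append(
                Spectrum(wn[order], sub["absorbance"].to_numpy(dtype=float)[order],
                         subject_id=str(sid), group=group)
            )
        return SpectralDataset(spectra)
    if format == "jcampdx":
        s = read_jcampdx(path)
        if s.subject_id in labels:
            s = replace(s, group=labels[s.subject_id])
        return SpectralDataset([s])
    raise ValueError(f"unknown format {format!r}")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a single spectrum from a minimal ``##XYDATA=(X++(Y..Y))`` JCAMP-DX file."""
    header: dict[str, str] = {}
    ys: list[float] = []
    xs: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise SpectraFormatError(
                        f"unsupported XYDATA dialect {value.strip()!r}"
                    )
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value.strip()
        elif in_data:
            fields = line.replace(",", " ").split()
            xs.append(float(fields[0]))
            ys.extend(float(v) for v in fields[1:])
    if not ys:
        raise SpectraFormatError("no XYDATA block found")
    try:
        firstx = float(header.get("FIRSTX", xs[0]))
        deltax = float(header["DELTAX"])
    except KeyError as exc:
        raise SpectraFormatError(f"missing JCAMP header ##{exc.args[0]}") from None
    yfactor = float(header.get("YFACTOR", 1.0))
    wn = firstx + deltax * np.arange(len(ys))
    _check_duplicate_wavenumbers(wn)
    title = header.get("TITLE", Path(path).stem)
    return Spectrum(wn, np.asarray(ys) * yfactor, subject_id=title)


def write_spectra(
    dataset: SpectralDataset,
    path: str | Path,
    format: Format = "csv_wide",
    manifest: str | Path | None = None,
) -> None:
    """Write ``dataset`` to ``path``; round-trips through :func:`read_spectra`.

    With ``format="csv_wide"`` an optional label ``manifest`` CSV is written
    alongside.  JCAMP-DX is read-only.
    """
    if format == "csv_wide":
        df = pd.DataFrame({"wavenumber": dataset.wavenumbers})
        for s in dataset:
            df[s.subject_id] = s.absorbance
        df.to_csv(path, index=False, float_format="%.17g")
        if manifest is not None:
            pd.DataFrame(
                {"subject_id": dataset.subject_ids, "group": dataset.groups}
            ).to_csv(manifest, index=False)
        return
    if format == "csv_long":
        frames = [
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "wavenumber": s.wavenumbers,
                    "absorbance": s.absorbance,
                }
            )
            for s in dataset
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )
        return
    raise ValueError(f"cannot write format {format!r}")


# ---------------------------------------------------------------------------
# grid alignment


def common_grid(
    spectra: SpectralDataset | Iterable[Spectrum], step: float | None = None
) -> SpectralDataset:
    """Linearly interpolate spectra onto one uniform ascending grid.

    Accepts a dataset or a plain iterable of spectra on *different* grids.
    The output grid covers the intersection of the individual ranges at
    spacing ``step`` (default: the median native spacing).  A dataset whose
    spectra already sit on the target grid is returned unchanged.
    """
    dataset = spectra if isinstance(spectra, SpectralDataset) else None
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if hi <= lo:
        raise ValueError(
            f"spectra do not overlap: intersection [{lo:g}, {hi:g}] cm^-1 is empty"
        )
    if step is None:
        step = float(np.median(np.concatenate([np.diff(s.wavenumbers) for s in spectra])))
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = lo + step * np.arange(n)
    same = all(
        len(s) == n and np.allclose(s.wavenumbers, grid, atol=1e-12) for s in spectra
    )
    if same and dataset is not None:
        return dataset
    return SpectralDataset(
        replace(s, wavenumbers=grid, absorbance=np.interp(grid, s.wavenumbers, s.absorbance))
        for s in spectra
    )


def average_replicates(spectra: Iterable[Spectrum], subject_id: str | None = None) -> Spectrum:
    """Pointwise mean of replicate spectra of one subject (optional utility)."""
    spectra = list(spectra)
    ds = SpectralDataset(spectra)  # validates shared grid
    mean = ds.to_matrix().mean(axis=0)
    first = spectra[0]
    return Spectrum(
        ds.wavenumbers,
        mean,
        subject_id=subject_id or first.subject_id,
        group=first.group,
    )
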