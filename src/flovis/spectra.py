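"""Reflectance / irradiance / sensitivity spectra on a common wavelength grid.

All downstream colour-vision computations assume spectra covering the
300-700 nm range sampled at 1 nm (the measurement range of typical
field spectrometry of flowers). This module reads delimited-text
spectral tables (wide: wavelength + one column per sample, the usual
FReD-style export; or long: sample/wavelength/value), validates them,
and provides resampling, replicate averaging and cleaning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COMMON_GRID",
    "Spectrum",
    "SpectrumSet",
    "SpectrumError",
    "read_spectra",
    "resample",
    "average_replicates",
    "clean",
]

#: Shared analysis grid: 300-700 nm at 1 nm (401 points).
COMMON_GRID: np.ndarray = np.arange(300.0, 701.0, 1.0)

#: How far (nm) a requested grid may poke beyond the measured range
#: before resampling refuses to extrapolate.
EXTRAPOLATION_TOLERANCE_NM = 5.0

SpectrumKind = Literal["reflectance", "irradiance", "sensitivity"]


class SpectrumError(ValueError):
    """Raised for malformed spectral data or invalid spectral operations."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function.

    Parameters
    ----------
    wavelengths:
        Strictly ascending wavelengths in nm.
    values:
        Nonnegative samples: reflectance as a fraction, irradiance in
        relative photon units, or sensitivity peak-normalised to 1.
    kind:
        One of ``reflectance``, ``irradiance``, ``sensitivity``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "reflectance"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise SpectrumError(
                f"wavelengths and values must be 1-D of equal length "
                f"(got {w.shape} and {v.shape})"
            )
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if np.any(np.diff(w) <= 0):
            raise SpectrumError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(v)):
            raise SpectrumError("spectral values must be finite")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def covers(self, lo: float = 300.0, hi: float = 700.0) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def value_at(self, wavelength: float) -> float:
        """Linear interpolation inside the measured range."""
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SpectrumSet:
    """A named collection of spectra of one kind.

    ``shared_grid`` is True when every member is sampled on an
    identical wavelength vector, which pointwise operations require.
    """

    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = {s.kind for s in self.spectra.values()}
        if len(kinds) > 1:
            raise SpectrumError(f"mixed spectrum kinds in one set: {sorted(kinds)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, key: str) -> Spectrum:
        return self.spectra[key]

    def __iter__(self):
        return iter(self.spectra)

    def items(self):
        return self.spectra.items()

    @property
    def shared_grid(self) -> bool:
        grids = [s.wavelengths for s in self.spectra.values()]
        return all(
            g.shape == grids[0].shape and np.array_equal(g, grids[0]) for g in grids
        )

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet({k: fn(s) for k, s in self.spectra.items()})


# ---------------------------------------------------------------------------
# reading


def _sniff_delimiter(sample: str) -> str:
    header = sample.splitlines()[0]
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _detect_scale(values: np.ndarray) -> float:
    # FReD and literature sources mix percent and fractional reflectance.
    return 100.0 if np.nanmax(values) > 1.5 else 1.0


def read_spectra(
    path: str | Path | io.StringIO,
    dialect: Literal["wide", "long"] = "wide",
    kind: SpectrumKind = "reflectance",
    percent: bool | None = None,
) -> SpectrumSet:
    """Read a delimited-text spectral table.

    ``wide``: first column is wavelength (nm), remaining columns one
    sample each.  ``long``: columns (sample, wavelength, value).
    Delimiter (comma/tab) is auto-detected; a header row is required.
    Reflectance recorded in percent is auto-detected (max > 1.5) and
    divided by 100 unless ``percent`` explicitly overrides.
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
        source = "<buffer>"
    else:
        source = str(path)
        text = Path(path).read_text(encoding="utf-8")
    sep = _sniff_delimiter(text)
    # keep cells verbatim so parse errors can name the offending token
    df = pd.read_csv(io.StringIO(text), sep=sep, header=0, dtype=str, na_filter=False)
    if df.shape[1] < 2:
        raise SpectrumError(f"{source}: expected at least two columns")

    if dialect == "long":
        if df.shape[1] < 3:
            raise SpectrumError(f"{source}: long dialect needs (sample, wavelength, value)")
        df = df.iloc[:, :3]
        df.columns = ["sample", "wavelength", "value"]
        for col in ("wavelength", "value"):
            df[col] = _to_numeric(df[col], source, col)
        dup = df.duplicated(subset=["sample", "wavelength"])
        if dup.any():
            row = df[dup].iloc[0]
            raise SpectrumError(
                f"{source}: duplicate (sample, wavelength) = "
                f"({row['sample']}, {row['wavelength']:g})"
            )
        out: dict[str, Spectrum] = {}
        for sample, grp in df.groupby("sample", sort=False):
            grp = grp.sort_values("wavelength")
            vals = grp["value"].to_numpy(float)
            scale = _detect_scale(vals) if percent is None else (100.0 if percent else 1.0)
            out[str(sample)] = Spectrum(
                grp["wavelength"].to_numpy(float), vals / scale, kind=kind
            )
        return SpectrumSet(out)

    if dialect != "wide":
        raise SpectrumError(f"unknown dialect {dialect!r}")

    wl_col = df.columns[0]
    wl = _to_numeric(df[wl_col], source, wl_col)
    if wl.duplicated().any():
        w = wl[wl.duplicated()].iloc[0]
        raise SpectrumError(f"{source}: duplicate wavelength {w:g}")
    order = np.argsort(wl.to_numpy())
    out = {}
    for col in df.columns[1:]:
        vals = _to_numeric(df[col], source, col).to_numpy(float)[order]
        scale = _detect_scale(vals) if percent is None else (100.0 if percent else 1.0)
        out[str(col)] = Spectrum(wl.to_numpy(float)[order], vals / scale, kind=kind)
    return SpectrumSet(out)


def _to_numeric(col: pd.Series, source: str, name) -> pd.Series:
    converted = pd.to_numeric(col, errors="coerce")
    bad = converted.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectrumError(
            f"{source}: non-numeric value {col.iloc[i]!r} "
            f"in column {name!r}, data row {i + 1}"
        )
    return converted.astype(float)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Write a shared-grid set as a wide CSV (wavelength + one column per sample)."""
    if not spectra.shared_grid:
        raise SpectrumError("write_spectra requires a shared grid; resample first")
    names = list(spectra)
    wl = spectra[names[0]].wavelengths
    df = pd.DataFrame({"wavelength": wl})
    for name in names:
        df[name] = spectra[name].values
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid operations


def resample(s: Spectrum, grid: np.ndarray = COMMON_GRID) -> Spectrum:
    """Linear interpolation onto ``grid``.

    Grid points up to 5 nm outside the measured range take the nearest
    measured value (small sensor-edge gaps are common); anything beyond
    that is treated as a data error rather than silently extrapolated.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.range
    if grid[0] < lo - EXTRAPOLATION_TOLERANCE_NM or grid[-1] > hi + EXTRAPOLATION_TOLERANCE_NM:
        raise SpectrumError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends more than "
            f"{EXTRAPOLATION_TOLERANCE_NM:g} nm beyond measured range [{lo:g}, {hi:g}]"
        )
    # np.interp clamps to end values, which is exactly the nearest-value fill.
    values = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, values, kind=s.kind)


def average_replicates(spectra: SpectrumSet | Iterable[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate measurements on a shared grid."""
    if isinstance(spectra, SpectrumSet):
        members = list(spectra.spectra.values())
        if members and not spectra.shared_grid:
            raise SpectrumError("replicates are on different grids; resample first")
    else:
        members = list(spectra)
        if members and not all(
            np.array_equal(m.wavelengths, members[0].wavelengths) for m in members
        ):
            raise SpectrumError("replicates are on different grids; resample first")
    if not members:
        raise SpectrumError("no replicates to average")
    stacked = np.vstack([m.values for m in members])
    return Spectrum(members[0].wavelengths, stacked.mean(axis=0), kind=members[0].kind)


def clean(s: Spectrum, smooth_window: int | None = None) -> Spectrum:
    """Clip negative values to zero; optionally boxcar-smooth.

    ``smooth_window`` is an odd number of grid steps; the window shrinks
    symmetrically at the edges so endpoints are averaged over fewer points.
    Metric integrals are computed on unsmoothed spectra by default; peak
    detection uses a 5-point boxcar (see :mod:`flovis.features`).
    """
    v = np.clip(s.values, 0.0, None)
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise SpectrumError("smooth_window must be an odd positive integer")
        half = smooth_window // 2
        out = np.empty_like(v)
        n = v.size
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = v[i - h : i + h + 1].mean()
        v = out
    return s.with_values(v)
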