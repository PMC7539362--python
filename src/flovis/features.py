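"""Spectral features of red flowers: the red criterion and the secondary peak.

"Red" here covers the red-orange shades that mainly reflect at long
wavelengths, operationalised with a 560 nm boundary. Many red flowers
additionally show a secondary reflectance peak (SP) in the UV or blue:
its relative intensity k — SP height divided by whole-spectrum height —
is the key quantitative trait, since an SP is what makes a red flower
chromatically detectable to pollinators lacking red photoreceptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectra import Spectrum, clean

__all__ = [
    "RED_BOUNDARY_NM",
    "RedClassification",
    "SPResult",
    "classify_red",
    "detect_sp",
    "classify_receptor_class",
    "DEFAULT_RECEPTOR_CLASS_MAP",
]

#: Long-wavelength boundary separating "red/orange" primary reflectance
#: from the short-wave region where a secondary peak may sit.
RED_BOUNDARY_NM = 560.0

#: Boxcar window (grid steps) applied before peak detection only; the
#: conspicuousness metrics are integrals and are computed unsmoothed.
PEAK_SMOOTH_WINDOW = 5

#: Local maxima with prominence below this fraction of the spectrum
#: height are treated as measurement ripple, not a secondary peak.
DEFAULT_MIN_PROMINENCE = 0.02


@dataclass(frozen=True)
class RedClassification:
    is_red: bool
    boundary: float
    long_wave_mean: float
    short_wave_mean: float
    peak_wavelength: float


@dataclass(frozen=True)
class SPResult:
    has_sp: bool
    sp_wavelength: float | None
    sp_height: float
    total_height: float
    k: float


def classify_red(s: Spectrum, boundary: float = RED_BOUNDARY_NM) -> RedClassification:
    """Classify a reflectance spectrum as red/orange.

    A spectrum is red when its primary reflectance is at long
    wavelengths: (a) the global reflectance maximum lies above the
    boundary, and (b) mean reflectance above the boundary exceeds mean
    reflectance below it. Both parts are invariant to uniform scaling,
    and a secondary short-wave peak does not disqualify a spectrum.
    """
    wl, v = s.wavelengths, np.clip(s.values, 0.0, None)
    above = wl > boundary
    if not above.any() or above.all():
        raise ValueError("spectrum must straddle the red boundary")
    peak_wl = float(wl[np.argmax(v)])
    long_mean = float(v[above].mean())
    short_mean = float(v[~above].mean())
    is_red = peak_wl > boundary and long_mean > short_mean
    return RedClassification(
        is_red=is_red,
        boundary=boundary,
        long_wave_mean=long_mean,
        short_wave_mean=short_mean,
        peak_wavelength=peak_wl,
    )


def detect_sp(
    s: Spectrum,
    boundary: float = RED_BOUNDARY_NM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    smooth_window: int | None = PEAK_SMOOTH_WINDOW,
) -> SPResult:
    """Detect the secondary reflectance peak and its intensity ratio k.

    The SP is the highest local maximum strictly below the boundary
    whose prominence is at least ``min_prominence`` times the spectrum
    height. Heights are absolute reflectance values (not height above a
    local baseline), so k = sp_height / total_height lies in [0, 1] and
    is invariant to uniform scaling of the spectrum. A spectrum that is
    monotone below the boundary (a pure sigmoidal red) has no SP and
    k = 0.
    """
    smoothed = clean(s, smooth_window=smooth_window)
    wl, v = smoothed.wavelengths, smoothed.values
    total = float(v.max())
    if total <= 0:
        return SPResult(False, None, 0.0, 0.0, 0.0)
    below = wl < boundary
    idx_below = np.flatnonzero(below)
    # search on the full curve so a maximum right at the window edge is
    # judged against its true neighbourhood, then keep sub-boundary peaks
    peaks, _ = find_peaks(v, prominence=min_prominence * total)
    peaks = peaks[np.isin(peaks, idx_below)]
    if peaks.size == 0:
        return SPResult(False, None, 0.0, total, 0.0)
    best = peaks[np.argmax(v[peaks])]
    sp_h = float(v[best])
    return SPResult(
        has_sp=True,
        sp_wavelength=float(wl[best]),
        sp_height=sp_h,
        total_height=total,
        k=sp_h / total,
    )


# ---------------------------------------------------------------------------
# pollinator receptor classes

#: Default mapping from pollinator group to red-photoreceptor class.
#: Birds and flower-visiting beetles possess long-wavelength ("red")
#: photoreceptors (R+); bees do not (R-). Butterfly colour vision is
#: too variable for a family-level default, so butterflies need an
#: explicit per-taxon entry (e.g. "butterfly:Danaus" -> R-).
DEFAULT_RECEPTOR_CLASS_MAP: dict[str, str] = {
    "bird": "R+",
    "hummingbird": "R+",
    "sunbird": "R+",
    "beetle": "R+",
    "bee": "R-",
    "butterfly:Danaus": "R-",
}


def classify_receptor_class(
    pollinator_group: str, mapping: dict[str, str] | None = None
) -> str:
    """Map a pollinator group label to {R+, R-, unclassified}.

    Deterministic lookup in the (possibly user-supplied) mapping table;
    unknown groups return "unclassified" rather than raising, since
    taxa with uncertain colour vision are a normal part of the data.
    """
    table = DEFAULT_RECEPTOR_CLASS_MAP if mapping is None else mapping
    return table.get(pollinator_group, "unclassified")
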