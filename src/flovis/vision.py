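"""Pollinator colour-vision models: quantum catches, colour loci and contrasts.

Two model families are implemented. The colour hexagon (CH) is the
classic trichromatic bee space: von-Kries-adapted quantum catches are
passed through the hyperbolic receptor transform ``E = q / (1 + q)``
and projected into a 2-D equilateral-hexagon plane whose origin is the
adapting (green-foliage) background; distances are in CH units. The
receptor-noise-limited (RNL) model applies to both trichromats and
tetrachromats: colour distance is limited by per-channel Weber
fractions ω and expressed in just-noticeable differences (JND), with
1 JND the theoretical discrimination threshold. Achromatic (intensity)
contrast uses a single channel — the green receptor in bees, the
double cone in birds — in Weber units. Spectral purity is the ratio of
a stimulus's distance from the background locus to the distance of the
same-hue monochromatic light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .spectra import COMMON_GRID, Spectrum, SpectrumError, resample

__all__ = [
    "Receptor",
    "Viewer",
    "ViewingContext",
    "CatchVector",
    "HexagonLocus",
    "TetraLocus",
    "VisionError",
    "pigment_template",
    "viewer_from_config",
    "context_from_config",
    "quantum_catch",
    "ch_locus",
    "ch_distance",
    "rnl_contrast",
    "weber_from_abundances",
    "achromatic_contrast",
    "spectrum_locus",
    "purity",
    "tetra_locus",
]


class VisionError(ValueError):
    """Raised for model-mismatch or degenerate visual computations."""


# ---------------------------------------------------------------------------
# visual-system building blocks


def pigment_template(lambda_max: float, grid: np.ndarray = COMMON_GRID) -> Spectrum:
    """Vitamin-A1 visual-pigment absorbance template (α band).

    Uses the Govardovskii rhodopsin template: absorbance at wavelength λ
    is a function of x = λmax/λ with universal constants, which places
    the peak at λmax and reproduces the asymmetric long-wave tail of
    real photoreceptor sensitivities. The returned spectrum is
    peak-normalised to 1 on the grid.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise VisionError(f"lambda_max {lambda_max:g} nm outside [300, 700]")
    grid = np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    s = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    s = s / s.max()
    return Spectrum(grid, s, kind="sensitivity")


@dataclass(frozen=True)
class Receptor:
    """A photoreceptor channel: spectral sensitivity plus Weber fraction ω."""

    name: str
    sensitivity: Spectrum
    lambda_max: float
    weber: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weber <= 1.0:
            raise VisionError(f"receptor {self.name}: weber must be in (0, 1]")
        if self.sensitivity.kind != "sensitivity":
            raise VisionError(f"receptor {self.name}: sensitivity spectrum required")
        v = self.sensitivity.values
        if np.any(v < 0) or not np.isclose(v.max(), 1.0, atol=1e-6):
            raise VisionError(
                f"receptor {self.name}: sensitivity must be nonnegative, peak 1"
            )


@dataclass(frozen=True)
class Viewer:
    """An ordered receptor set with a distinct achromatic channel.

    Receptors are ordered by ascending λmax (UV/blue/green for the bee
    trichromat; SWS1/SWS2/MWS/LWS for avian tetrachromats). The
    achromatic channel is physiologically separate from the chromatic
    mechanism: the green receptor in bees, the double cone in birds.
    """

    name: str
    receptors: tuple[Receptor, ...]
    achromatic_receptor: Receptor
    model_family: Literal["trichromat", "tetrachromat"]

    def __post_init__(self) -> None:
        n = len(self.receptors)
        expected = {"trichromat": 3, "tetrachromat": 4}[self.model_family]
        if n != expected:
            raise VisionError(
                f"{self.model_family} viewer needs {expected} receptors, got {n}"
            )
        lmaxes = [r.lambda_max for r in self.receptors]
        if lmaxes != sorted(lmaxes):
            raise VisionError("receptors must be ordered by ascending lambda_max")

    @property
    def webers(self) -> np.ndarray:
        return np.array([r.weber for r in self.receptors])

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)


@dataclass(frozen=True)
class ViewingContext:
    """Illumination and adapting background against which stimuli are seen."""

    illuminant: Spectrum
    background: Spectrum

    def __post_init__(self) -> None:
        for label, s, lo_ok in (
            ("illuminant", self.illuminant, False),
            ("background", self.background, True),
        ):
            if not s.covers(300.0, 700.0):
                raise VisionError(f"{label} must cover [300, 700] nm")
        ill = resample(self.illuminant, COMMON_GRID)
        if np.any(ill.values <= 0):
            raise VisionError("illuminant must be strictly positive on the grid")


@dataclass(frozen=True)
class CatchVector:
    """Raw and background-adapted (von Kries) quantum catches per receptor."""

    raw: np.ndarray
    adapted: np.ndarray
    viewer: Viewer
    ach_raw: float
    ach_adapted: float


def viewer_from_config(path) -> Viewer:
    """Build a viewer from a YAML definition file.

    Schema::

        name: my_bird
        model_family: tetrachromat
        receptors:              # ascending lambda_max
          - {name: SWS1, lambda_max: 371, weber: 0.2}
          - {name: SWS2, lambda_max: 445, weber: 0.1414}
          - {name: MWS,  lambda_max: 508, weber: 0.1414}
          - {name: LWS,  lambda_max: 605, weber: 0.1}
        achromatic: {name: double-cone, lambda_max: 563, weber: 0.05}

    A receptor may give ``sensitivity_path`` (wide CSV, first sample
    column used) instead of ``lambda_max`` to load a tabulated curve.
    """
    import yaml

    from .spectra import read_spectra

    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))

    def build(rc: dict) -> Receptor:
        if "sensitivity_path" in rc:
            ss = read_spectra(rc["sensitivity_path"], kind="sensitivity")
            s = resample(ss[next(iter(ss))], COMMON_GRID)
            s = Spectrum(s.wavelengths, s.values / s.values.max(), kind="sensitivity")
            lmax = float(s.wavelengths[int(np.argmax(s.values))])
        else:
            lmax = float(rc["lambda_max"])
            s = pigment_template(lmax)
        return Receptor(rc["name"], s, lmax, float(rc["weber"]))

    receptors = tuple(build(rc) for rc in cfg["receptors"])
    return Viewer(
        name=cfg.get("name", "custom"),
        receptors=receptors,
        achromatic_receptor=build(cfg["achromatic"]),
        model_family=cfg["model_family"],
    )


def context_from_config(path) -> ViewingContext:
    """Build a viewing context from a YAML file naming spectra files.

    Schema: ``illuminant: <wide CSV path or "flat">`` and
    ``background: <wide CSV path>``.
    """
    import yaml

    from .spectra import read_spectra

    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if cfg["illuminant"] == "flat":
        ill = Spectrum(COMMON_GRID, np.ones(COMMON_GRID.size), kind="irradiance")
    else:
        ss = read_spectra(cfg["illuminant"], kind="irradiance")
        ill = resample(ss[next(iter(ss))], COMMON_GRID)
    bg_set = read_spectra(cfg["background"])
    bg = resample(bg_set[next(iter(bg_set))], COMMON_GRID)
    return ViewingContext(illuminant=ill, background=bg)


# ---------------------------------------------------------------------------
# photon catch


def _integrate_catch(reflectance: np.ndarray, sensitivity: np.ndarray,
                     illuminant: np.ndarray, grid: np.ndarray) -> float:
    return float(np.trapezoid(reflectance * sensitivity * illuminant, grid))


def quantum_catch(reflectance: Spectrum, viewer: Viewer, ctx: ViewingContext) -> CatchVector:
    """Photon catches of a stimulus, von-Kries-adapted to the background.

    The raw catch of receptor i is the trapezoid integral over
    300-700 nm of R(λ)·S_i(λ)·I(λ). The adapted catch divides by the
    catch of the adapting background, so the background itself maps to
    q = 1 in every channel and uniform scaling of the illuminant cancels.
    """
    grid = COMMON_GRID
    refl = resample(reflectance, grid).values
    ill = resample(ctx.illuminant, grid).values
    bg = resample(ctx.background, grid).values

    receptors = list(viewer.receptors) + [viewer.achromatic_receptor]
    raw = np.empty(len(receptors))
    adapted = np.empty(len(receptors))
    for i, rec in enumerate(receptors):
        sens = resample(rec.sensitivity, grid).values
        q_bg = _integrate_catch(bg, sens, ill, grid)
        if q_bg <= 0:
            raise VisionError(
                f"background yields zero catch in receptor {rec.name}; "
                "degenerate von Kries adaptation"
            )
        raw[i] = _integrate_catch(refl, sens, ill, grid)
        adapted[i] = raw[i] / q_bg
    return CatchVector(
        raw=raw[:-1], adapted=adapted[:-1], viewer=viewer,
        ach_raw=float(raw[-1]), ach_adapted=float(adapted[-1]),
    )


# ---------------------------------------------------------------------------
# colour hexagon (trichromat)


@dataclass(frozen=True)
class HexagonLocus:
    """Colour-hexagon coordinates; the adapting background sits at (0, 0)."""

    E: np.ndarray  # receptor signals, one per (UV, blue, green)
    x: float
    y: float

    @property
    def distance_to_origin(self) -> float:
        return float(np.hypot(self.x, self.y))


def receptor_signal(q: np.ndarray) -> np.ndarray:
    """Hyperbolic receptor transform E = q/(1+q), saturating at 1."""
    q = np.asarray(q, dtype=float)
    return q / (1.0 + q)


def _hexagon_xy(E: np.ndarray) -> tuple[float, float]:
    e_uv, e_blue, e_green = E
    x = (np.sqrt(3.0) / 2.0) * (e_green - e_uv)
    y = e_blue - (e_uv + e_green) / 2.0
    return float(x), float(y)


def ch_locus(catches: CatchVector) -> HexagonLocus:
    """Colour-hexagon locus of a stimulus (trichromatic viewers only)."""
    if catches.viewer.model_family != "trichromat":
        raise VisionError("colour hexagon is defined for trichromatic viewers only")
    E = receptor_signal(catches.adapted)
    x, y = _hexagon_xy(E)
    return HexagonLocus(E=E, x=x, y=y)


def ch_distance(a: HexagonLocus, b: HexagonLocus | None = None) -> float:
    """Euclidean distance in CH units; against the background origin if b is None."""
    if b is None:
        return a.distance_to_origin
    return float(np.hypot(a.x - b.x, a.y - b.y))


# ---------------------------------------------------------------------------
# receptor-noise-limited model


def rnl_contrast(target: CatchVector, viewer: Viewer | None = None) -> float:
    """Chromatic distance of a stimulus from its background in JND.

    Receptor signals are log-transformed adapted catches, Δf_i = ln q_i
    (the background contributes Δf = 0 under von Kries adaptation), and
    combined through the receptor-noise opponent quadratic forms for
    three or four channels with Weber fractions ω as the noise terms.
    """
    viewer = viewer or target.viewer
    q = np.asarray(target.adapted, dtype=float)
    if np.any(q <= 0):
        raise VisionError("adapted catches must be strictly positive for the RNL model")
    df = np.log(q)
    w = viewer.webers
    return rnl_distance(df, w)


def rnl_distance(df: np.ndarray, w: np.ndarray) -> float:
    """Receptor-noise-limited distance for a signal difference vector Δf."""
    df = np.asarray(df, dtype=float)
    w = np.asarray(w, dtype=float)
    if df.size != w.size:
        raise VisionError("signal and noise vectors must have equal length")
    if df.size == 3:
        f1, f2, f3 = df
        w1, w2, w3 = w
        num = (
            w1 ** 2 * (f3 - f2) ** 2
            + w2 ** 2 * (f3 - f1) ** 2
            + w3 ** 2 * (f2 - f1) ** 2
        )
        den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
        return float(np.sqrt(num / den))
    if df.size == 4:
        f1, f2, f3, f4 = df
        w1, w2, w3, w4 = w
        num = (
            (w1 * w2) ** 2 * (f4 - f3) ** 2
            + (w1 * w3) ** 2 * (f4 - f2) ** 2
            + (w1 * w4) ** 2 * (f3 - f2) ** 2
            + (w2 * w3) ** 2 * (f4 - f1) ** 2
            + (w2 * w4) ** 2 * (f3 - f1) ** 2
            + (w3 * w4) ** 2 * (f2 - f1) ** 2
        )
        den = (
            (w1 * w2 * w3) ** 2
            + (w1 * w2 * w4) ** 2
            + (w1 * w3 * w4) ** 2
            + (w2 * w3 * w4) ** 2
        )
        return float(np.sqrt(num / den))
    raise VisionError(f"RNL closed forms implemented for 3 or 4 receptors, got {df.size}")


def weber_from_abundances(
    omega_ref: float, ref_index: int, abundances: Sequence[float]
) -> np.ndarray:
    """Derive per-channel Weber fractions from relative receptor abundances.

    Receptor noise scales inversely with the square root of the number
    of receptors per channel, so ω_i = ω_ref · sqrt(η_ref / η_i).
    The reference channel keeps ω_ref exactly.
    """
    eta = np.asarray(abundances, dtype=float)
    if np.any(eta <= 0):
        raise VisionError("receptor abundances must be strictly positive")
    if not 0 <= ref_index < eta.size:
        raise VisionError("ref_index out of range")
    return omega_ref * np.sqrt(eta[ref_index] / eta)


def achromatic_contrast(target: CatchVector, viewer: Viewer | None = None) -> float:
    """Intensity contrast in the achromatic channel, in Weber units.

    Flower-background contrast in the achromatic receptor (green
    receptor for bees, double cone for birds), |ln q_ach|, divided by
    that channel's Weber fraction.
    """
    viewer = viewer or target.viewer
    q = target.ach_adapted
    if q <= 0:
        raise VisionError("achromatic catch must be strictly positive")
    return float(abs(np.log(q)) / viewer.achromatic_receptor.weber)


# ---------------------------------------------------------------------------
# spectrum locus and purity (trichromat)


def spectrum_locus(
    viewer: Viewer, ctx: ViewingContext, step: float = 1.0
) -> list[HexagonLocus]:
    """Colour-hexagon loci of monochromatic lights across 300-700 nm.

    The receptor signal E depends on stimulus intensity, so a
    convention is required for monochromatic lights: each is scaled so
    its summed raw catch across the viewer's receptors equals that of
    the adapting background, which keeps the locus (and hence purity)
    invariant under uniform illuminant scaling. Returned in wavelength
    order; used as the outer boundary for the purity computation.
    """
    if viewer.model_family != "trichromat":
        raise VisionError("spectrum locus implemented for trichromatic viewers")
    grid = COMMON_GRID
    ill = resample(ctx.illuminant, grid).values
    bg = resample(ctx.background, grid).values
    sens = np.vstack(
        [resample(r.sensitivity, grid).values for r in viewer.receptors]
    )
    q_bg = np.array(
        [_integrate_catch(bg, sens[i], ill, grid) for i in range(sens.shape[0])]
    )
    if np.any(q_bg <= 0):
        raise VisionError("background yields zero catch in a receptor")
    bg_total = q_bg.sum()

    loci: list[HexagonLocus] = []
    wavelengths = np.arange(300.0, 700.0 + 1e-9, step)
    for lam in wavelengths:
        # catch of a narrow line at lam is proportional to S_i(lam) * I(lam)
        raw = np.array([np.interp(lam, grid, sens[i]) for i in range(sens.shape[0])])
        raw = raw * np.interp(lam, grid, ill)
        total = raw.sum()
        if total <= 0:
            continue  # outside every receptor's sensitivity support
        raw = raw * (bg_total / total)
        E = receptor_signal(raw / q_bg)
        x, y = _hexagon_xy(E)
        loci.append(HexagonLocus(E=E, x=x, y=y))
    if len(loci) < 3:
        raise VisionError("spectrum locus degenerate: fewer than 3 valid wavelengths")
    return loci


def _ray_segment_scale(px: float, py: float, ax: float, ay: float,
                       bx: float, by: float) -> float | None:
    """Scale t > 0 such that t*(px,py) lies on segment a-b, or None."""
    dx, dy = bx - ax, by - ay
    det = px * (-dy) - py * (-dx)
    if abs(det) < 1e-15:
        return None
    # solve t*p = a + u*(b-a)
    t = (ax * (-dy) + ay * dx) / det
    u = (px * ay - py * ax) / det
    if t > 1e-12 and -1e-9 <= u <= 1.0 + 1e-9:
        return t
    return None


def purity(locus: HexagonLocus, sl: Sequence[HexagonLocus]) -> float:
    """Spectral purity: |locus| / |same-hue point on the spectrum locus|.

    The ray from the origin through the stimulus locus is intersected
    with the piecewise-linear spectrum-locus polyline closed by the
    purple line joining its UV and red ends; purity is the ratio of the
    stimulus distance to the intersection distance. The origin
    (background colour) has purity 0 by convention.
    """
    r = locus.distance_to_origin
    if r == 0.0:
        return 0.0
    px, py = locus.x / r, locus.y / r
    pts = [(p.x, p.y) for p in sl]
    pts_closed = pts + [pts[0]]  # purple-line closure
    best: float | None = None
    for (ax, ay), (bx, by) in zip(pts_closed[:-1], pts_closed[1:]):
        t = _ray_segment_scale(px, py, ax, ay, bx, by)
        if t is not None and (best is None or t < best):
            best = t
    if best is None:
        raise VisionError(
            "ray from origin misses the closed spectrum locus; malformed locus"
        )
    return float(r / best)


# ---------------------------------------------------------------------------
# tetrahedral colour space (tetrachromat)

# Regular tetrahedron with centroid at the origin and unit circumradius;
# rows are vertices for receptors ordered SWS1, SWS2, MWS, LWS.
_TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 1.0],
        [2.0 * np.sqrt(2.0) / 3.0, 0.0, -1.0 / 3.0],
        [-np.sqrt(2.0) / 3.0, np.sqrt(2.0 / 3.0), -1.0 / 3.0],
        [-np.sqrt(2.0) / 3.0, -np.sqrt(2.0 / 3.0), -1.0 / 3.0],
    ]
)


@dataclass(frozen=True)
class TetraLocus:
    """Tetrahedral colour-space locus; equal catches map to the origin."""

    relative: np.ndarray  # usml catches normalised to sum 1
    x: float
    y: float
    z: float

    @property
    def distance_to_origin(self) -> float:
        return float(np.sqrt(self.x ** 2 + self.y ** 2 + self.z ** 2))


def tetra_locus(catches: CatchVector) -> TetraLocus:
    """Barycentric embedding of adapted catches in a regular tetrahedron.

    Catches are normalised to relative proportions summing to 1; the
    achromatic point (1/4, 1/4, 1/4, 1/4) maps to the origin and each
    single-receptor vertex lies at distance 1 (unit circumradius).
    """
    if catches.viewer.model_family != "tetrachromat":
        raise VisionError("tetrahedral space is defined for tetrachromatic viewers")
    q = np.asarray(catches.adapted, dtype=float)
    total = q.sum()
    if total <= 0:
        raise VisionError("all catches zero: degenerate stimulus")
    rel = q / total
    # affine map: centroid of vertices is 0, so rel @ V sends (1/4,...) to origin
    xyz = rel @ _TETRA_VERTICES
    return TetraLocus(relative=rel, x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]))
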