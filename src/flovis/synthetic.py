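"""Synthetic study inputs: flower spectra, viewers, backgrounds, trees, communities.

Field reflectance archives rarely ship raw curves, so every input the
analysis needs can be generated here under seed control:

* red flower spectra — a logistic long-wavelength rise (inflection
  above 560 nm) with an optional Gaussian secondary peak (SP) in the
  UV/blue whose relative height k is specified on the noiseless curve
  and calibrated numerically against :func:`flovis.features.detect_sp`;
* a green-foliage adapting background and flat or daylight-like
  illuminants;
* the four pollinator visual systems used throughout (bumblebee
  trichromat; UVS bird, VS bird and hummingbird tetrachromats) with
  their published Weber fractions;
* Yule trees and group-structured communities in which the SP
  intensity distribution differs between pollination systems.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.optimize import brentq

from .features import RED_BOUNDARY_NM, detect_sp
from .spectra import COMMON_GRID, Spectrum, SpectrumSet
from .vision import Receptor, Viewer, ViewingContext, pigment_template, weber_from_abundances

__all__ = [
    "SpectrumParams",
    "GroupSpec",
    "CommunityScenario",
    "make_flower_spectrum",
    "make_leaf_background",
    "make_illuminant",
    "make_viewer",
    "make_context",
    "make_tree",
    "make_community",
]


class ParameterError(ValueError):
    """Raised when generator parameters are infeasible."""


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class SpectrumParams:
    """Parameters of a synthetic red-flower reflectance spectrum.

    The long-wavelength rise is logistic with the given amplitude,
    inflection (> 560 nm for red) and steepness, on top of a small flat
    ``baseline`` reflectance (petal tissue never reflects exactly
    zero); ``sp_relative_height`` is the target k of the secondary
    peak as measured by :func:`flovis.features.detect_sp` on the
    noiseless curve. Noise is additive Gaussian, clipped to [0, 1].
    """

    base_amplitude: float = 0.6
    baseline: float = 0.03
    inflection: float = 620.0
    steepness: float = 15.0
    sp_center: float | None = 440.0
    sp_width: float = 30.0
    sp_relative_height: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.base_amplitude <= 1.0:
            raise ParameterError("base_amplitude must be in (0, 1]")
        if not 0.0 <= self.sp_relative_height <= 1.0:
            raise ParameterError("sp_relative_height must be in [0, 1]")
        if self.sp_center is not None and self.sp_center >= RED_BOUNDARY_NM:
            raise ParameterError("sp_center must lie below the red boundary")


def _logistic_base(grid: np.ndarray, amp: float, infl: float, steep: float) -> np.ndarray:
    return amp / (1.0 + np.exp(-(grid - infl) / steep))


def make_flower_spectrum(p: SpectrumParams) -> Spectrum:
    """Generate a red reflectance spectrum with a controlled SP intensity.

    The Gaussian SP amplitude is solved numerically (bisection) so that
    the detected k on the noiseless curve matches
    ``sp_relative_height``; this accounts for the overlap between the
    logistic base and the SP flank. Seeded Gaussian noise is added
    afterwards and the result clipped to [0, 1].
    """
    grid = COMMON_GRID
    base = p.baseline + _logistic_base(
        grid, p.base_amplitude - p.baseline, p.inflection, p.steepness
    )
    target = p.sp_relative_height

    if target == 0.0 or p.sp_center is None:
        values = base
    else:
        gauss = np.exp(-((grid - p.sp_center) ** 2) / (2.0 * p.sp_width ** 2))

        def detected_k(h: float) -> float:
            return detect_sp(Spectrum(grid, np.clip(base + h * gauss, 0.0, 1.0))).k

        h_max = 1.0  # SP peak can at most reach full reflectance
        if detected_k(h_max) < target - 1e-6:
            raise ParameterError(
                f"target k={target:g} unreachable with sp_center={p.sp_center:g}"
            )
        # detected k is 0 below the prominence floor; bracket from there
        lo = 0.0
        h = brentq(lambda h: detected_k(h) - target, lo, h_max, xtol=1e-6)
        values = np.clip(base + h * gauss, 0.0, 1.0)

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        values = values + rng.normal(0.0, p.noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(values, 0.0, 1.0))


def make_leaf_background(seed: int | None = None) -> Spectrum:
    """Green-foliage reflectance: low baseline with a chlorophyll bump near 550 nm.

    Stands in for an averaged leaf reflectance: ~5% baseline plus a
    Gaussian green peak of ~10% amplitude. Deterministic when ``seed``
    is None; a seed adds small measurement-like ripple.
    """
    grid = COMMON_GRID
    v = 0.05 + 0.10 * np.exp(-((grid - 550.0) ** 2) / (2.0 * 40.0 ** 2))
    if seed is not None:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, 0.002, size=grid.size)
    return Spectrum(grid, np.clip(v, 1e-4, 0.3))


def make_illuminant(kind: str = "flat") -> Spectrum:
    """Illuminant spectrum: ``flat`` (equal photon flux) or ``daylight_like``.

    Under von Kries adaptation every metric is invariant to uniform
    illuminant scaling, so the flat default keeps fixtures
    self-contained without affecting contrasts of broadband stimuli
    much.
    """
    grid = COMMON_GRID
    if kind == "flat":
        v = np.ones_like(grid)
    elif kind == "daylight_like":
        # smooth broadband curve, weaker in the UV, mildly peaked mid-spectrum
        v = 0.3 + 0.7 * np.exp(-((grid - 480.0) ** 2) / (2.0 * 150.0 ** 2))
    else:
        raise ParameterError(f"unknown illuminant kind {kind!r}")
    return Spectrum(grid, v, kind="irradiance")


# ---------------------------------------------------------------------------
# viewers

#: Receptor peak sensitivities (nm) for each modelled visual system.
#: Bee values follow bumblebee (Bombus terrestris) electrophysiology;
#: bird SWS1 peaks follow the UVS/VS opsin classes (371 / 406 nm, with
#: the hummingbird at 370 nm per electroretinogram evidence) and the
#: LWS peak is set at 605 nm within the published 601-620 nm range.
VIEWER_LAMBDA_MAX: dict[str, tuple[float, ...]] = {
    "bee": (347.0, 424.0, 539.0),
    "uvs_bird": (371.0, 445.0, 508.0, 605.0),
    "vs_bird": (406.0, 450.0, 508.0, 605.0),
    "hummingbird": (370.0, 440.0, 508.0, 605.0),
}

#: Chromatic Weber fractions. Bee values are the published bumblebee
#: noise estimates for UV/blue/green; bird values derive from an LWS
#: Weber fraction of 0.1 and relative single-cone abundances via
#: ``weber_from_abundances`` (UVS 1:2:2:4, VS 2:2:2:4).
BEE_WEBERS = (0.74, 0.67, 0.61)
BIRD_LWS_WEBER = 0.1
BIRD_CONE_ABUNDANCES = {
    "uvs_bird": (1.0, 2.0, 2.0, 4.0),
    "vs_bird": (2.0, 2.0, 2.0, 4.0),
    "hummingbird": (1.0, 2.0, 2.0, 4.0),
}

#: Achromatic-channel Weber fractions: bee green receptor 0.61,
#: avian double cone 0.05.
BEE_ACHROMATIC_WEBER = 0.61
BIRD_DOUBLE_CONE_WEBER = 0.05
BIRD_DOUBLE_CONE_LMAX = 563.0

_BEE_RECEPTOR_NAMES = ("UV", "blue", "green")
_BIRD_RECEPTOR_NAMES = ("SWS1", "SWS2", "MWS", "LWS")


def make_viewer(kind: str = "bee") -> Viewer:
    """Build one of the four standard pollinator visual systems.

    Receptor sensitivities come from the visual-pigment template at the
    peaks in :data:`VIEWER_LAMBDA_MAX`. The bee achromatic channel is
    its own green receptor (ω = 0.61); birds use a double cone
    (λmax 563 nm, ω = 0.05).
    """
    if kind == "bee":
        receptors = tuple(
            Receptor(name, pigment_template(lmax), lmax, w)
            for name, lmax, w in zip(
                _BEE_RECEPTOR_NAMES, VIEWER_LAMBDA_MAX["bee"], BEE_WEBERS
            )
        )
        ach = Receptor(
            "green-achromatic",
            pigment_template(VIEWER_LAMBDA_MAX["bee"][2]),
            VIEWER_LAMBDA_MAX["bee"][2],
            BEE_ACHROMATIC_WEBER,
        )
        return Viewer("bee", receptors, ach, "trichromat")
    if kind in ("uvs_bird", "vs_bird", "hummingbird"):
        lmaxes = VIEWER_LAMBDA_MAX[kind]
        webers = weber_from_abundances(
            BIRD_LWS_WEBER, 3, BIRD_CONE_ABUNDANCES[kind]
        )
        receptors = tuple(
            Receptor(name, pigment_template(lmax), lmax, float(w))
            for name, lmax, w in zip(_BIRD_RECEPTOR_NAMES, lmaxes, webers)
        )
        ach = Receptor(
            "double-cone",
            pigment_template(BIRD_DOUBLE_CONE_LMAX),
            BIRD_DOUBLE_CONE_LMAX,
            BIRD_DOUBLE_CONE_WEBER,
        )
        return Viewer(kind, receptors, ach, "tetrachromat")
    raise ParameterError(f"unknown viewer kind {kind!r}")


def make_context(illuminant: str = "flat", background_seed: int | None = None) -> ViewingContext:
    """Standard viewing context: chosen illuminant over the green-leaf background."""
    return ViewingContext(
        illuminant=make_illuminant(illuminant),
        background=make_leaf_background(background_seed),
    )


# ---------------------------------------------------------------------------
# trees and communities


def make_tree(n_tips: int, rate: float = 1.0, seed: int | None = None) -> dendropy.Tree:
    """Seeded Yule (pure-birth) tree with tips labelled sp1..spN.

    The simulator stops at the n-th birth, which would leave one
    zero-length sister pair (and a singular tip covariance); the tree
    is therefore run on for the exponential waiting time to the next
    birth, keeping it ultrametric with strictly positive tip branches.
    """
    if n_tips < 2:
        raise ParameterError("a tree needs at least two tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    extra = rng.expovariate(rate * n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree


@dataclass(frozen=True)
class GroupSpec:
    """One pollination-system group in a synthetic community."""

    label: str
    n_species: int
    k_mean: float
    k_sd: float
    pollination_system: str
    continent: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ParameterError("each group needs at least two species")


@dataclass(frozen=True)
class CommunityScenario:
    """A group-structured community of red flowers on a shared phylogeny.

    Defaults mirror the sampling design of large red-flower surveys:
    a small bee-pollinated group with intense secondary peaks, an Old
    World bird group with intermediate SPs and a larger New World bird
    group with weak SPs.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("bee", 10, 0.60, 0.15, "bee", "OW"),
        GroupSpec("ow_bird", 37, 0.30, 0.15, "sunbird", "OW"),
        GroupSpec("nw_bird", 47, 0.10, 0.08, "hummingbird", "NW"),
    )
    tree_rate: float = 1.0
    base_amplitude: float = 0.6
    noise_sd: float = 0.005
    seed: int = 0


def make_community(
    sc: CommunityScenario,
) -> tuple[SpectrumSet, pd.DataFrame, dendropy.Tree]:
    """Generate spectra, metadata and a tree for a community scenario.

    Per-species k values are drawn from each group's normal
    distribution, clipped to the feasible [0, 0.95] range; species are
    assigned to tree tips in a seeded random order so group structure
    is not aligned with tree topology (traits are exchangeable across
    the phylogeny under the null). Metadata records group, pollination
    system, continent, the realised target k and all seeds.
    """
    ss = np.random.SeedSequence(sc.seed)
    tree_seed, k_seed, order_seed, *spec_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + sum(g.n_species for g in sc.groups))
    ]
    n_total = sum(g.n_species for g in sc.groups)
    tree = make_tree(n_total, rate=sc.tree_rate, seed=tree_seed)

    rng_k = np.random.default_rng(k_seed)
    rows = []
    for g in sc.groups:
        ks = np.clip(rng_k.normal(g.k_mean, g.k_sd, size=g.n_species), 0.0, 0.95)
        for k in ks:
            rows.append(
                {
                    "group": g.label,
                    "pollination_system": g.pollination_system,
                    "continent": g.continent,
                    "k_target": float(k),
                }
            )
    rng_order = np.random.default_rng(order_seed)
    order = rng_order.permutation(n_total)
    labels = [f"sp{i + 1}" for i in range(n_total)]
    meta = pd.DataFrame([rows[j] for j in order], index=labels)
    meta.index.name = "species"

    spectra = {}
    for (label, row), seed in zip(meta.iterrows(), spec_seeds):
        p = SpectrumParams(
            base_amplitude=sc.base_amplitude,
            sp_relative_height=row["k_target"],
            noise_sd=sc.noise_sd,
            seed=seed,
        )
        spectra[label] = make_flower_spectrum(p)
    meta.attrs["seed"] = sc.seed
    meta.attrs["tree_seed"] = tree_seed
    meta.attrs["k_seed"] = k_seed
    return SpectrumSet(spectra), meta, tree
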