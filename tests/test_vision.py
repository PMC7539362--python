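import numpy as np
import pytest

from flovis import synthetic as syn
from flovis import vision
from flovis.spectra import COMMON_GRID, Spectrum
from flovis.vision import (
    CatchVector,
    HexagonLocus,
    Receptor,
    Viewer,
    ViewingContext,
    VisionError,
    achromatic_contrast,
    ch_distance,
    ch_locus,
    pigment_template,
    purity,
    quantum_catch,
    receptor_signal,
    rnl_contrast,
    rnl_distance,
    spectrum_locus,
    tetra_locus,
    weber_from_abundances,
)


def rnl_noise_oracle(df, w):
    """Independent RNL distance: Mahalanobis length of the signal vector
    after projecting out the achromatic (equal-shift) direction.

    The noise-limited distance is the minimum over achromatic shifts c of
    sum_i (df_i - c)^2 / w_i^2, attained at the noise-weighted mean.
    """
    inv = 1.0 / np.asarray(w, float) ** 2
    c = float((df * inv).sum() / inv.sum())
    return float(np.sqrt((((df - c) ** 2) * inv).sum()))


def _gaussian_sensitivity(center, sigma=40.0):
    v = np.exp(-((COMMON_GRID - center) ** 2) / (2 * sigma**2))
    return Spectrum(COMMON_GRID, v / v.max(), kind="sensitivity")


@pytest.fixture(scope="module")
def gaussian_viewer():
    recs = tuple(
        Receptor(n, _gaussian_sensitivity(c), c, 0.5)
        for n, c in zip(("a", "b", "c"), (350.0, 450.0, 550.0))
    )
    return Viewer("gauss", recs, recs[2], "trichromat")


@pytest.fixture(scope="module")
def flat_ctx():
    flat = Spectrum(COMMON_GRID, np.ones(COMMON_GRID.size), kind="irradiance")
    bg = Spectrum(COMMON_GRID, np.full(COMMON_GRID.size, 0.5))
    return ViewingContext(illuminant=flat, background=bg)


class TestQuantumCatch:
    def test_von_kries_identity_on_background(self, bee, ctx):
        c = quantum_catch(ctx.background, bee, ctx)
        np.testing.assert_allclose(c.adapted, 1.0, atol=1e-12)
        assert c.ach_adapted == pytest.approx(1.0, abs=1e-12)

    def test_linearity_in_reflectance(self, bee, ctx, red_spectrum):
        c1 = quantum_catch(red_spectrum, bee, ctx)
        doubled = red_spectrum.with_values(red_spectrum.values * 2)
        c2 = quantum_catch(doubled, bee, ctx)
        np.testing.assert_allclose(c2.adapted, 2 * c1.adapted, rtol=1e-12)

    def test_raw_catch_matches_fine_grid_oracle(self, gaussian_viewer, flat_ctx):
        """Unit reflectance, flat illuminant: Q is the area under each
        sensitivity curve, checked against 0.01-nm analytic integration."""
        ones = Spectrum(COMMON_GRID, np.ones(COMMON_GRID.size))
        c = quantum_catch(ones, gaussian_viewer, flat_ctx)
        fine = np.arange(300.0, 700.0 + 0.01, 0.01)
        for i, center in enumerate((350.0, 450.0, 550.0)):
            g = np.exp(-((fine - center) ** 2) / (2 * 40.0**2))
            oracle = np.trapezoid(g / g.max(), fine)
            assert c.raw[i] == pytest.approx(oracle, rel=1e-4)

    def test_degenerate_background_rejected(self, bee):
        flat = Spectrum(COMMON_GRID, np.ones(COMMON_GRID.size), kind="irradiance")
        zero_bg = Spectrum(COMMON_GRID, np.zeros(COMMON_GRID.size))
        ctx = ViewingContext(illuminant=flat, background=zero_bg)
        ones = Spectrum(COMMON_GRID, np.ones(COMMON_GRID.size))
        with pytest.raises(VisionError, match="zero catch"):
            quantum_catch(ones, bee, ctx)

    def test_illuminant_scaling_cancels(self, bee, red_spectrum):
        """von Kries: all metrics invariant to uniform illuminant scaling."""
        bg = syn.make_leaf_background()
        flat = syn.make_illuminant("flat")
        bright = flat.with_values(flat.values * 7.3)
        c1 = quantum_catch(red_spectrum, bee, ViewingContext(flat, bg))
        c2 = quantum_catch(red_spectrum, bee, ViewingContext(bright, bg))
        np.testing.assert_allclose(c1.adapted, c2.adapted, rtol=1e-12)
        assert rnl_contrast(c1) == pytest.approx(rnl_contrast(c2), rel=1e-12)
        assert achromatic_contrast(c1) == pytest.approx(achromatic_contrast(c2), rel=1e-12)


class TestColourHexagon:
    def test_background_maps_to_origin(self, bee, ctx):
        c = quantum_catch(ctx.background, bee, ctx)
        locus = ch_locus(c)
        np.testing.assert_allclose(locus.E, 0.5, atol=1e-12)
        assert locus.x == pytest.approx(0.0, abs=1e-12)
        assert locus.y == pytest.approx(0.0, abs=1e-12)

    def test_receptor_signal_saturates_at_one(self):
        q = np.array([1e-12, 1.0, 1e12])
        E = receptor_signal(q)
        assert E[0] == pytest.approx(0.0, abs=1e-9)
        assert E[1] == pytest.approx(0.5)
        assert E[2] == pytest.approx(1.0, abs=1e-9)
        assert np.all((E >= 0) & (E <= 1))

    def test_receptor_signal_strictly_increasing(self):
        q = np.linspace(0.01, 50, 500)
        assert np.all(np.diff(receptor_signal(q)) > 0)

    def test_pure_green_signal_at_unit_distance(self, bee, ctx):
        """E = (0, 0, 1) lies one CH unit from the background origin."""
        c = quantum_catch(ctx.background, bee, ctx)
        saturated = CatchVector(
            raw=c.raw, adapted=np.array([1e-15, 1e-15, 1e15]), viewer=bee,
            ach_raw=c.ach_raw, ach_adapted=1.0,
        )
        locus = ch_locus(saturated)
        assert ch_distance(locus) == pytest.approx(1.0, abs=1e-6)

    def test_tetrachromat_rejected(self, uvs_bird, ctx):
        c = quantum_catch(ctx.background, uvs_bird, ctx)
        with pytest.raises(VisionError, match="trichromat"):
            ch_locus(c)

    def test_distance_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = [
                HexagonLocus(E=np.zeros(3), x=float(x), y=float(y))
                for x, y in rng.uniform(-1, 1, size=(3, 2))
            ]
            a, b, c = pts
            assert ch_distance(a, b) == pytest.approx(ch_distance(b, a))
            assert ch_distance(a, c) <= ch_distance(a, b) + ch_distance(b, c) + 1e-12
        assert ch_distance(pts[0], pts[0]) == 0.0


class TestRNL:
    def test_background_is_zero_jnd(self, bee, ctx):
        c = quantum_catch(ctx.background, bee, ctx)
        assert rnl_contrast(c) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4])
    def test_closed_forms_match_noise_oracle(self, n):
        """The printed tri-/tetrachromatic quadratic forms agree with the
        generic receptor-noise construction to 1e-9 over 1000 random draws."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            df = rng.normal(0, 2, n)
            w = rng.uniform(0.02, 1.0, n)
            got = rnl_distance(df, w)
            want = rnl_noise_oracle(df, w)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_doubling_noise_halves_distance(self):
        df = np.array([0.4, -0.2, 0.1])
        w = np.array([0.3, 0.2, 0.1])
        assert rnl_distance(df, 2 * w) == pytest.approx(rnl_distance(df, w) / 2)

    def test_nonpositive_catch_rejected(self, bee):
        c = CatchVector(
            raw=np.ones(3), adapted=np.array([1.0, 0.0, 1.0]), viewer=bee,
            ach_raw=1.0, ach_adapted=1.0,
        )
        with pytest.raises(VisionError):
            rnl_contrast(c)


class TestWeberFromAbundances:
    def test_uvs_bird_vector(self):
        """LWS omega 0.1 with 1:2:2:4 single-cone abundances gives the
        published UVS-bird Weber fractions (0.2, 0.1414, 0.1414, 0.1)."""
        w = weber_from_abundances(0.1, 3, [1.0, 2.0, 2.0, 4.0])
        assert w[0] == pytest.approx(0.2)
        assert round(w[1], 4) == 0.1414
        assert round(w[2], 4) == 0.1414
        assert w[3] == 0.1

    def test_vs_bird_sws1(self):
        w = weber_from_abundances(0.1, 3, [2.0, 2.0, 2.0, 4.0])
        assert round(w[0], 4) == 0.1414

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(VisionError):
            weber_from_abundances(0.1, 0, [1.0, -2.0])


class TestAchromaticContrast:
    def test_background_is_zero(self, bee, ctx):
        c = quantum_catch(ctx.background, bee, ctx)
        assert achromatic_contrast(c) == pytest.approx(0.0, abs=1e-12)

    def test_catch_of_e_with_bird_double_cone(self, uvs_bird):
        """ln(e)/0.05 = 20 Weber units for the avian double cone."""
        c = CatchVector(
            raw=np.ones(4), adapted=np.ones(4), viewer=uvs_bird,
            ach_raw=1.0, ach_adapted=float(np.e),
        )
        assert achromatic_contrast(c) == pytest.approx(20.0)

    def test_ignores_chromatic_channels(self, bee):
        rng = np.random.default_rng(7)
        base = CatchVector(
            raw=np.ones(3), adapted=np.ones(3), viewer=bee,
            ach_raw=1.0, ach_adapted=2.0,
        )
        for _ in range(5):
            other = CatchVector(
                raw=np.ones(3), adapted=rng.uniform(0.1, 5, 3), viewer=bee,
                ach_raw=1.0, ach_adapted=2.0,
            )
            assert achromatic_contrast(other) == achromatic_contrast(base)


class TestSpectrumLocusAndPurity:
    def test_endpoints_exist_and_differ(self, bee_spectrum_locus):
        first, last = bee_spectrum_locus[0], bee_spectrum_locus[-1]
        assert (first.x, first.y) != (last.x, last.y)

    def test_monochromatic_loci_are_extremal(self, bee, ctx):
        """Mixtures of neighbouring monochromatic lights lie no farther
        from the origin than the more distant component."""
        sl = spectrum_locus(bee, ctx, step=5.0)
        for a, b in zip(sl[:-1], sl[1:]):
            for wgt in (0.25, 0.5, 0.75):
                qa = a.E / (1 - a.E)
                qb = b.E / (1 - b.E)
                E_mix = receptor_signal(wgt * qa + (1 - wgt) * qb)
                x = (np.sqrt(3) / 2) * (E_mix[2] - E_mix[0])
                y = E_mix[1] - (E_mix[0] + E_mix[2]) / 2
                d_mix = float(np.hypot(x, y))
                assert d_mix <= max(ch_distance(a), ch_distance(b)) + 1e-9

    def test_each_receptor_dominates_somewhere(self, bee_spectrum_locus):
        winners = {int(np.argmax(p.E)) for p in bee_spectrum_locus}
        assert winners == {0, 1, 2}

    def test_purity_of_point_on_locus_is_one(self, bee_spectrum_locus):
        p = bee_spectrum_locus[len(bee_spectrum_locus) // 2]
        assert purity(p, bee_spectrum_locus) == pytest.approx(1.0, abs=1e-6)

    def test_purity_of_origin_is_zero(self, bee_spectrum_locus):
        origin = HexagonLocus(E=np.full(3, 0.5), x=0.0, y=0.0)
        assert purity(origin, bee_spectrum_locus) == 0.0

    def test_purity_scales_linearly_toward_locus(self, bee_spectrum_locus):
        p = bee_spectrum_locus[len(bee_spectrum_locus) // 3]
        half = HexagonLocus(E=p.E, x=p.x / 2, y=p.y / 2)
        assert purity(half, bee_spectrum_locus) == pytest.approx(0.5, abs=1e-6)

    def test_flower_purity_in_unit_interval(self, bee, ctx, bee_spectrum_locus):
        for k in (0.0, 0.3, 0.7):
            s = syn.make_flower_spectrum(syn.SpectrumParams(sp_relative_height=k))
            locus = ch_locus(quantum_catch(s, bee, ctx))
            assert 0.0 <= purity(locus, bee_spectrum_locus) <= 1.0


class TestTetraLocus:
    def test_equal_catches_at_origin(self, uvs_bird):
        c = CatchVector(
            raw=np.ones(4), adapted=np.ones(4), viewer=uvs_bird,
            ach_raw=1.0, ach_adapted=1.0,
        )
        t = tetra_locus(c)
        assert t.distance_to_origin == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t.relative, 0.25)

    @pytest.mark.parametrize("axis", [0, 1, 2, 3])
    def test_single_catch_reaches_unit_vertex(self, uvs_bird, axis):
        q = np.zeros(4)
        q[axis] = 3.7
        c = CatchVector(raw=q, adapted=q, viewer=uvs_bird, ach_raw=1.0, ach_adapted=1.0)
        assert tetra_locus(c).distance_to_origin == pytest.approx(1.0)

    def test_vertices_equidistant(self, uvs_bird):
        verts = []
        for axis in range(4):
            q = np.zeros(4)
            q[axis] = 1.0
            c = CatchVector(raw=q, adapted=q, viewer=uvs_bird, ach_raw=1.0, ach_adapted=1.0)
            t = tetra_locus(c)
            verts.append(np.array([t.x, t.y, t.z]))
        dists = [
            np.linalg.norm(verts[i] - verts[j])
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        np.testing.assert_allclose(dists, dists[0], rtol=1e-12)

    def test_all_zero_catches_rejected(self, uvs_bird):
        c = CatchVector(
            raw=np.zeros(4), adapted=np.zeros(4), viewer=uvs_bird,
            ach_raw=0.0, ach_adapted=0.0,
        )
        with pytest.raises(VisionError, match="degenerate"):
            tetra_locus(c)


class TestConfigLoaders:
    def test_viewer_yaml_roundtrip(self, tmp_path):
        cfg = """
name: my_bird
model_family: tetrachromat
receptors:
  - {name: SWS1, lambda_max: 371, weber: 0.2}
  - {name: SWS2, lambda_max: 445, weber: 0.1414}
  - {name: MWS,  lambda_max: 508, weber: 0.1414}
  - {name: LWS,  lambda_max: 605, weber: 0.1}
achromatic: {name: double-cone, lambda_max: 563, weber: 0.05}
"""
        path = tmp_path / "viewer.yaml"
        path.write_text(cfg)
        v = vision.viewer_from_config(path)
        assert v.model_family == "tetrachromat"
        np.testing.assert_allclose(v.webers, [0.2, 0.1414, 0.1414, 0.1])
        assert v.achromatic_receptor.weber == 0.05

    def test_context_yaml_with_flat_illuminant(self, tmp_path):
        import pandas as pd

        bg = syn.make_leaf_background()
        pd.DataFrame({"wavelength": bg.wavelengths, "leaf": bg.values}).to_csv(
            tmp_path / "bg.csv", index=False
        )
        (tmp_path / "ctx.yaml").write_text(
            f"illuminant: flat\nbackground: {tmp_path / 'bg.csv'}\n"
        )
        ctx = vision.context_from_config(tmp_path / "ctx.yaml")
        np.testing.assert_array_equal(ctx.illuminant.values, 1.0)
        np.testing.assert_allclose(ctx.background.values, bg.values, atol=1e-9)


class TestPigmentTemplate:
    def test_peak_normalised(self):
        s = pigment_template(540.0)
        assert s.values.max() == pytest.approx(1.0)
        assert s.value_at(540.0) == pytest.approx(1.0, abs=1e-3)

    def test_peak_position_within_1nm(self):
        s = pigment_template(540.0)
        peak = s.wavelengths[np.argmax(s.values)]
        assert abs(peak - 540.0) <= 1.0

    @pytest.mark.parametrize("lmax", [350.0, 450.0, 560.0, 605.0])
    def test_unimodal(self, lmax):
        s = pigment_template(lmax)
        d = np.diff(s.values)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
        assert sign_changes <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(VisionError):
            pigment_template(250.0)
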