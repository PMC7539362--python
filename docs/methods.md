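# Methods

This note documents the models implemented in `flovis`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Spectra

All analysis happens on a common grid of 300–700 nm at 1 nm
(401 points), the range covered by field spectrometry of flowers.
Input tables (wide or long delimited text) are validated strictly:
non-numeric cells and duplicate (sample, wavelength) pairs are errors
that name their location, because silent coercion of archive exports
is a classic source of corrupt colour metrics. Reflectance recorded in
percent is auto-detected (maximum > 1.5) and rescaled, with an
explicit override. Resampling is linear interpolation; grid points up
to 5 nm outside the measured range take the nearest measured value
(sensor-edge gaps are common in archive spectra), anything beyond is a
coverage error rather than an extrapolation. Replicate averaging is a
pointwise mean on a shared grid.

Smoothing policy: conspicuousness metrics are wavelength integrals and
therefore noise-robust, so they are computed on *unsmoothed* spectra.
Peak detection is not noise-robust, so it applies a 5-point boxcar
(shrinking symmetrically at the edges) first. Whether a given archive
spectrum was already smoothed at digitisation is usually unknowable,
so the window is configurable.

## Visual systems

Receptor sensitivities are generated from the Govardovskii vitamin-A1
α-band template, peak-normalised on the grid. Template-based receptors
keep the package self-contained and agree with tabulated sensitivities
to within the tolerances that matter for broadband stimuli.

| viewer | λmax (nm) | chromatic ω | achromatic channel |
|---|---|---|---|
| bee (trichromat) | 347, 424, 539 | 0.74, 0.67, 0.61 | green receptor, ω = 0.61 |
| UVS bird | 371, 445, 508, 605 | 0.2, 0.1414, 0.1414, 0.1 | double cone (563 nm), ω = 0.05 |
| VS bird | 406, 450, 508, 605 | 0.1414, 0.1414, 0.1414, 0.1 | double cone, ω = 0.05 |
| hummingbird | 370, 440, 508, 605 | 0.2, 0.1414, 0.1414, 0.1 | double cone, ω = 0.05 |

Bee peaks follow bumblebee (*Bombus terrestris*) electrophysiology and
the bee ω values are the published UV/blue/green noise estimates. Bird
ω vectors are *derived*, not hard-coded: from the LWS reference
ω = 0.1 and relative single-cone abundances η (UVS 1:2:2:4,
VS 2:2:2:4) via ω_i = ω_LWS √(η_LWS/η_i); the derivation is itself a
tested operation. The avian LWS peak is set at 605 nm, inside the
601–620 nm range reported for birds; SWS2/MWS peaks (445/450, 508 nm)
are representative values for the two avian classes — group contrasts
are insensitive to a few nm here. The hummingbird SWS1 sits at 370 nm
following electroretinogram evidence, which groups hummingbirds with
the UVS class even though their opsin sequence is VS-like; both a
`hummingbird` and a `vs_bird` viewer are provided so either assumption
can be used.

The bee achromatic divisor is the green-receptor Weber fraction
(0.61). An argument could be made for a separate green-contrast noise
value; the receptor's own ω is used because achromatic contrast is
defined here as green-channel contrast divided by "the Weber fraction
of the corresponding photoreceptor", and it is configurable by
constructing a `Viewer` with a different achromatic receptor.

## Colour spaces and contrasts

Quantum catches are trapezoid integrals on the 1-nm grid (validated
against 0.01-nm integration; relative error ≲ 1e−4 for smooth
curves). Von Kries adaptation divides by the background catch, so the
background maps exactly to q = 1, the hexagon origin, and 0 JND; all
metrics are invariant to uniform illuminant scaling.

The RNL signal transform is logarithmic, Δf = ln q — the standard
Weber-fraction form and the natural pairing with a noise model
expressed in relative thresholds. Distances use the tri- and
tetrachromatic opponent quadratic forms; both are cross-checked (to
1e−9) against an independent construction: the minimum over achromatic
shifts of the noise-weighted residual, i.e. the Mahalanobis length of
Δf after projecting out the intensity direction.

Spectral purity requires a convention for monochromatic-light
intensity, because the hexagon transform is intensity-dependent. Each
monochromatic light is scaled so its summed raw catch across the
viewer's receptors equals that of the adapting background. This keeps
the spectrum locus — and hence purity — invariant under illuminant
scaling and places every broadband stimulus inside the locus. The
locus polyline is closed with the purple line joining its UV and red
ends so that every ray from the origin intersects it; purity of the
origin is 0 by convention.

The tetrahedral space for birds embeds relative catches
(normalised to sum 1) in a regular tetrahedron with the achromatic
point (¼,¼,¼,¼) at the origin and unit circumradius.

## Red classification and the secondary peak

"Red" (including orange shades) is operationalised with a 560 nm
boundary: a spectrum is red when its global maximum lies above the
boundary *and* mean reflectance above the boundary exceeds the mean
below. Both clauses are scale-invariant, and a secondary peak does not
disqualify a spectrum.

The secondary peak (SP) is the highest local maximum strictly below
the boundary with prominence at least 2 % of the spectrum height —
a floor that rejects instrument ripple while keeping genuinely weak
SPs; a monotone (pure sigmoidal) spectrum has no SP. Its intensity
k is SP height divided by whole-spectrum height, with "height"
meaning absolute reflectance at the peak rather than height above a
local baseline: this is the simplest reading of a peak-height ratio,
keeps k in [0, 1] and preserves scale invariance. The SP search window
[300, 560) covers both the UV and the blue SP classes; users who need
the two-class distinction can split on `sp_wavelength` < 400 nm.

Pollinator groups map to receptor classes (R+ = has red
photoreceptors, R− = lacks them) through an explicit table: birds and
flower-visiting beetles R+, bees R−. Butterfly colour vision is not
conservative even at family level, so butterflies require a per-taxon
entry (e.g. `butterfly:Danaus` → R−) and are otherwise "unclassified"
— a value, not an error.

## Phylogenetic statistics

The tip covariance C of a rooted tree has C[i,j] equal to the shared
root-to-MRCA path length (multifurcations and zero-length branches are
handled; ultrametricity is not required). Brownian-motion simulation
draws from N(0, σ²C) via Cholesky (eigenvalue fallback for
semidefinite C).

**Phylogenetic ANOVA.** The observed one-way F statistic is referred
to a null distribution of F values computed from BM replicates
simulated on the tree with group labels held fixed. The BM rate is the
phylogenetic ML estimator σ̂² = (y−μ̂)ᵀC⁻¹(y−μ̂)/n with μ̂ the GLS
mean (the F statistic is scale-free, so this choice affects nothing
but reporting). The p-value convention is (1+m)/(n+1), which cannot
return exactly zero. Pairwise post-hoc t statistics (pooled MSE) are
referred two-sidedly to their own simulated nulls and Holm-adjusted
within each test family — i.e. within one metric × viewer comparison,
not across metrics.

**PGLS with Pagel's λ.** V(λ) multiplies the off-diagonals of C by
λ ∈ [0,1]. The λ profile (ML by default; REML by flag) is maximised by
bounded scalar optimisation with tolerance 1e−6, with an explicit
boundary check so λ̂ = 0 or 1 is returned exactly when a boundary is
optimal. λ is restricted to [0,1] for interpretability and validity of
the transform. Coefficients are GLS via Cholesky whitening; R² is
1 − RSS/TSS in the whitened space around the GLS intercept-only fit;
the slope p-value is a two-sided t test with n − p degrees of freedom.
At λ = 0 the fit reduces exactly to OLS (tested to 1e−8).

## Synthetic data

The generator emulates the structure of a red-flower community study;
its defaults are the study conditions used by the analysis drivers and
tests.

* **Flower spectra**: logistic long-wavelength rise (amplitude 0.6,
  inflection 620 nm, steepness 15 nm) on a flat 3 % baseline — petal
  tissue never reflects exactly zero, and without this floor
  log-signal contrasts for bees diverge unrealistically. The SP is a
  Gaussian (centre 440 nm, width 30 nm) whose amplitude is solved by
  bisection so that the *detected* k on the noiseless curve equals the
  requested value: the generator's contract is defined in terms of the
  package's own detector, which makes round-trips exactly testable
  (recovered within ±0.02 across k = 0…1). Requested k below the
  detector's prominence floor (≈0.03 of spectrum height) is not
  representable; targets of 0.1 and above are safe. Noise is additive
  Gaussian, clipped to [0, 1].
* **Background**: 5 % baseline plus a 10 % Gaussian green bump at
  550 nm — a synthetic stand-in for an averaged leaf reflectance.
* **Illuminant**: flat (equal-energy) by default; a smooth
  daylight-like curve is available. Von Kries adaptation makes all
  metrics invariant to illuminant scale, and for broadband stimuli the
  choice between these two barely moves group contrasts.
* **Trees**: seeded Yule trees. The simulator stops at the n-th
  birth, which would leave a zero-length sister pair and a singular
  covariance; tip branches are therefore extended by the exponential
  waiting time to the next birth.
* **Communities**: per-group k distributions (normal, clipped to
  [0, 0.95]); the default scenario has 10 bee-pollinated species with
  mean k 0.6, 37 Old World bird species with 0.3 and 47 New World bird
  species with 0.1. Species are assigned to tips in seeded random
  order, so group structure is *not* phylogenetically clustered:
  under the null the traits are exchangeable across tips, and λ̂ in
  PGLS fits on these communities is correctly near 0. Continent labels
  are metadata only; the continent effect is mediated entirely by the
  k distributions.

What the generator does **not** emulate: pigment-level (anthocyanin)
chemistry and its correlated spectral constraints; phylogenetic signal
in spectral traits (groups are exchangeable by design, so tests that
pass here say nothing about λ estimation on clustered real data —
that is covered separately by BM-simulation recovery tests);
instrument noise structure (real spectrometer noise is
wavelength-dependent); or mixed/uncertain pollination records.
Passing tests on synthetic communities demonstrate that the machinery
detects the effects it is pointed at, with calibrated error rates —
not that any particular biological effect size is realistic.

One known interaction: the achromatic channel overlaps the SP region
(bee green receptor and avian double cone both have short-wave
flanks), so synthetic groups that differ in k also differ somewhat in
achromatic contrast even at constant spectrum amplitude. This is a
property of receptor overlap, not a bug; real surveys that report no
achromatic group differences involve amplitude variation that this
generator holds fixed.

## Validation problem sizes

The statistical calibration suite uses: star-tree agreement with
classical ANOVA at 10,000 null simulations (±0.02); type-I error of
the phylogenetic ANOVA over 2,000 BM datasets on a 30-tip Yule tree at
1,000 simulations each (0.05 ± 0.01); Pagel's-λ recovery as the mean
of 200 ML fits on one 200-tip Yule tree with λ = 1 residuals (mean in
[0.9, 1.0]); RNL oracle agreement on 1,000 random draws each for
n = 3 and n = 4. These sizes give Monte-Carlo error comfortably inside
each tolerance while keeping the default test run fast.
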