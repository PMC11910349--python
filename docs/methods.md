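# Methods

## Dose model

Dose is approximated by collisional kerma: at Ir-192 energies
(60–1100 keV photon lines, mean ≈ 350 keV) secondary-electron ranges in
tissue are short compared with millimetre voxels, so charged-particle
equilibrium holds everywhere except microscopically close to interfaces,
and kerma is an accurate surrogate for absorbed dose.  No electron
transport is performed.

Photons are transported individually.  Free paths are sampled per voxel
from the local linear attenuation μ = (μ/ρ)·ρ along an Amanatides–Woo
traversal of the grid; every traversed chord scores

K(v) += w · E · ℓ · (μ_en/ρ)(E, medium(v)) / V_voxel

which is the track-length (fluence) estimator of collisional kerma per
unit mass.  An analog interaction-density estimator (score
w·E·(μ_en/ρ)/(μ·V) at collision sites) is provided solely as an
independent cross-check; the two agree within statistics on slab
phantoms.

Interactions: photoelectric absorption terminates the photon (no
fluorescence — the K X-rays of tissue elements are below the transport
cutoff); Compton scattering samples the free-electron Klein–Nishina
distribution (no binding, no Doppler broadening); Rayleigh scattering
resamples the direction from a Wentzel screened-form-factor angular
distribution with a per-material effective screening radius, leaving the
energy unchanged.  Photons are discarded below 10 keV (kerma is already
accounted along the track, so nothing is deposited at termination).
These simplifications matter little above ~60 keV and affect both
schemes identically; the endpoints are *paired relative* differences.

## Two tissue-assignment schemes, one engine

* **Unbound water (D_w,w).**  Every voxel — patient and surrounding
  air — is water at density 1.0.  A photon leaving the grid continues in
  an analytic infinite water bath (no scoring) and may scatter back in,
  emulating the infinite homogeneous phantom assumed by TG-43-style
  planning.  The grid content is deliberately ignored.
* **Heterogeneous (D_m,m).**  Each voxel receives a tissue class and a
  piecewise-linearly interpolated density from a HU calibration curve
  (bundled default anchors: air −1000 / 0.0012, lung −700 / 0.26,
  adipose −98 / 0.93, soft tissue 14 / 1.03 and 100 / 1.10, bone
  300 / 1.35 and 2000 / 2.1 g/cm³; user-replaceable).  Class boundaries
  sit at midpoints between adjacent anchors of different class; a HU on
  a boundary joins the higher class.  Breast voxels override the class:
  adipose, or a 50/50 adipose–gland mixture inside the glandular mask.
  The mixture is by **mass** (mass fractions averaged, density the
  mass-weighted harmonic mean); volume-fraction mixing would change the
  mixture density by ~0.1% and is not offered.  A photon leaving the
  grid is discarded: beyond the scoring volume lies air, whose
  backscatter is negligible.

Both doses come from the same engine, the same plan, the same photon
spectrum and the same master seed, so every per-case difference is due to
the scheme alone.  Volumes use the voxel-center rule throughout (a voxel
belongs to a structure iff its center is inside the contour), so DVHs of
the two schemes are computed on identical voxel sets.

## Source model and absolute normalization

Each dwell position is a bare isotropic point source emitting the bundled
Ir-192 line spectrum (17 γ lines plus grouped Os/Pt K X-rays, 2.31
photons/decay; β continua and conversion electrons are irrelevant to
photon kerma and omitted).  No source capsule, cable, or anisotropy is
modelled — a declared simplification relative to clinical source models;
it cancels to first order in paired comparisons.

Absolute dose: the plan's air-kerma strength S_k (μGy·m²/h) is divided by
the free-space air-kerma rate at 1 m per unit decay rate — computed from
the same spectrum and air μ_en/ρ tables — giving the decay rate, hence
decays per dwell, hence Gy.  With S_k = 40 000 U this yields
3.7×10¹¹ decays/s (≈10 Ci) and an implied dose-rate constant of
~1.13 cGy·h⁻¹·U⁻¹ at 1 cm, both in the expected range for HDR Ir-192
sources.  Histories are allocated to dwells proportionally to their
decays (largest-remainder rounding, every active dwell gets at least one
history per batch), so the estimator stays unbiased.

## Cross-section data

Per-element tables (H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca) on a
60-point log grid over 10–1500 keV are bundled as plain text and
assembled into material tables by Bragg additivity; interpolation is
log-log linear.  The tables are generated by
`scripts/build_xs_tables.py` from analytic physics: Klein–Nishina
incoherent scattering, a Wentzel screened-form-factor coherent cross
section, a fitted power-law photoelectric term (σ ∝ Z^4.5 E^−3.25,
calibrated on water at 10 keV), and μ_en built from photoelectric plus
the Klein–Nishina mean energy-transfer fraction (radiative losses
neglected, g ≲ 0.5% below 1.5 MeV in low-Z media).  Spot checks against
standard tabulations: water μ/ρ at 1 MeV 0.0714 vs 0.0707 cm²/g, water
μ_en/ρ ≈ 0.0312 vs 0.0309 cm²/g, water/air μ_en ratio at 400 keV 1.112.
Accuracy degrades below ~60 keV (several percent), where photoelectric
details and binding corrections matter; this is adequate for comparative
kerma dosimetry at Ir-192 energies but is not an EPDL97 replacement.

## Statistics

Each run is split into B batches (default 10); per-voxel batch sums and
sums of squares give the standard error of the total, and the Type-A
uncertainty report averages SE/dose over the voxels within ±1% of a
reference isodose (the band half-width is a declared choice; the set of
voxels "on" an isodose surface is otherwise ambiguous).

Per-case differences use (w − m)/m × 100, positive when the all-water
calculation overestimates.  Cohorts are summarized by the median and
range of the *per-case* differences (not differences of medians).  The
Wilcoxon signed-rank test discards zero differences (Pratt handling
available), uses mid-ranks for ties, and reports a two-sided p — exact by
dynamic-programming enumeration of all 2^n sign assignments for n ≤ 20,
and a tie-corrected normal approximation with continuity correction
beyond.

## Synthetic cohort

The generator emulates the *statistical structure* of a post-lumpectomy
interstitial implant population, not CT realism:

* hemispherical breast (radius U(50, 90) mm) of adipose-range HU on a
  soft-tissue chest-wall slab (15 mm) over a low-density lung slab
  (40 mm), air elsewhere; the slabs span the full lateral grid because
  the thorax continues beyond the scoring volume;
* glandular blobs: Gaussian-filtered noise thresholded to the requested
  glandularity fraction (U(0.1, 0.5)) of breast volume;
* a spherical excision cavity (radius U(10, 25) mm, soft-tissue HU)
  whose surface sits U(3, 20) mm beneath the skin along a random
  upper-hemisphere direction — lumpectomy beds are commonly superficial,
  which is what places targets near the tissue–air interface;
* skin = outer 2 mm rim of the body; CTV/PTV = cavity dilated by
  10/15 mm (Euclidean), clipped to breast-side tissue with the chest
  wall and lung excluded; PTV_EVAL additionally removes the 5 mm rim
  beneath the body surface.  The CTV margin is a conventional value
  exposed as a parameter (the protocol literature defines PTV and
  PTV_EVAL, not a CTV margin);
* 10–25 parallel straight catheters (count uniform), laid on a lattice
  whose spacing adapts so the drawn count covers the whole target
  cross-section, as clinical implants do; dwells every 5 mm within the
  PTV + 5 mm;
* dwell times from a non-negative least-squares fit of an
  inverse-square-with-attenuation *water* kernel to the per-fraction
  prescription at PTV surface points, Tikhonov-regularized toward
  uniform times, then rescaled so the kernel-predicted PTV D90 equals
  the prescription.  Planning deliberately uses a water kernel, not the
  MC engine: clinical plans are made under water assumptions and then
  re-evaluated, and the pipeline preserves that causal design.  The
  regularization weight (1.0) was calibrated once so that generated
  plans match typical clinical plan quality under D_w,w (PTV V200
  ≈ 9–10%, V100 ≈ 92%, D90 ≈ 103%); without it, raw NNLS produces
  clinically implausible spiky dwell times;
* optional high-density catheter markers (bone-range HU, excluded from
  the breast override) reproduce the known segmentation artifact in
  which markers absorb dose as small bony features; off by default;
* everything derives from one integer seed; identical seeds give
  voxelwise-identical cases.

What passing tests on this cohort do show: the directional, paired
effects of replacing water by CT-derived tissues — signs, orderings, and
rough magnitudes of the DVH-metric differences.  What they cannot show:
clinical magnitudes for real anatomies (no ribs, no heart, no curved
chest wall, no free-hand catheter curvature, no CT artifacts), so the
package asserts sign structure and ordering, never clinical values.

## Numerical choices and problem sizes

* Voxels: 1 mm³ for benchmark phantoms; 2 mm (parameter) for synthetic
  cases, keeping a full two-scheme case ≈ seconds per 10⁵ histories.
* Default desk-scale runs: 10⁵–10⁶ histories, 5–10 batches; the cohort
  experiment in `scripts/acceptance.py` uses 8 cases × 5×10⁵ histories
  per scheme.  Statistical (Type-A) per-voxel uncertainty at the 100%
  isodose is then a few percent — the paired median differences it feeds
  are stable at the ±0.5% level across seeds.
* Energy lookups: materials are resampled onto a shared 1024-point
  log-energy grid inside the engine; table lookups outside the engine
  interpolate the native 60-point grids and refuse to extrapolate.
* Randomness: one master seed; a counter-based splitmix64 stream is
  derived per history, so results are bit-reproducible and independent
  of batch/dwell execution order.  Dose scales exactly linearly with
  dwell time and S_k.
* Tie-breaks chosen deterministically and documented in docstrings:
  boundary HU → higher class; voxel center on a contour → inside;
  dose exactly at a DVH level → counted (≥ convention); D_v cm³ = the
  discrete order statistic without interpolation; D-metrics normalized
  to the full-course prescription.

## Known limitations

Kerma approximation near interfaces (sub-voxel electron disequilibrium
at the skin surface is not modelled); simplified low-energy photon
physics; bare point source; no applicator/marker metal transport beyond
HU reclassification; synthetic anatomy as above; single-threaded
transport (numba-compiled; ~10⁶ full-scatter histories ≈ 6 s on one CPU
core for a 1.4M-voxel phantom).
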