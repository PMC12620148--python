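# Methods

This note documents the models implemented in `cestdisc`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical decisions that affect results.

## Spectral model

All Z-spectra — simulated and fitted — are Lorentzian superpositions:

    Z(Δω) = 1 − Σᵢ Aᵢ · (Γᵢ²/4) / ((Γᵢ²/4) + (Δω − δᵢ − ΔB₀)²)

with amplitude Aᵢ (peak depth in normalized Z units), FWHM Γᵢ (ppm) and
center δᵢ (ppm).  This is a steady-state approximation: no
Bloch–McConnell exchange dynamics, no saturation-power or duration
dependence, no T₁/T₂ relaxation terms.  It is adequate here because the
quantification stage fits the same functional family, so simulation and
analysis are self-consistent, and because the geometric pipeline only
needs spectra with a field-dependent minimum.  Conclusions about
absolute contrast magnitudes on real data do not follow from these
phantoms; conclusions about the geometry pipeline do.

Pool defaults (chosen once, on physical grounds, for a 3 T, ~0.8 µT CW
saturation regime):

| pool | A | Γ (ppm) | δ (ppm) | where |
|---|---|---|---|---|
| DS, DI-water phantom | 0.92 | 1.0 | 0 | creatine phantom |
| DS, tissue | 0.85 / 0.88 | 1.4 / 1.5 | 0 | brain / muscle |
| creatine amine | 0.002·mM | 1.0 | +2.0 | phantom tubes, 5–50 mM |
| amide | 0.045 (brain), 0.020 (muscle), 0.025 (tumor) | 1.5 | +3.5 | |
| rNOE | 0.060 / 0.030 / 0.035 | 3.0 | −3.5 | brain / muscle / tumor |
| MT | 0.10–0.12 | 25 | 0 | tissue only |

The phantom DS width deserves a comment: a DI-water sample has long T₂,
so the DS dip at 0.8 µT CW is dominated by saturation broadening
(≈ 2·γ·B₁ ≈ 0.5 ppm at 3 T) plus exchange and inhomogeneity broadening —
about 1 ppm FWHM, roughly half the tissue value.  Tumor amide/rNOE
amplitudes are set below contralateral tissue so both contrasts are
hypointense in the lesion, the direction the quantification tests check.
The broad MT pool is deliberately wide enough (Γ = 25 ppm) to be
absorbed by the DS fit's flat baseline; the residual slope it leaves
across the fit wings is a known, documented bias of the flat-baseline
choice (below).

## Field, distortion and noise

The ΔB₀ field is a low-order 2D polynomial (coordinates normalized to
[−1, 1]) plus Gaussian bumps, optionally randomly placed per seed;
realizations exceeding the configured bound (default 0.5 ppm, a typical
3 T shim residual; raise it explicitly for high-field-like regimes)
raise an error rather than being clipped.  The same per-voxel ΔB₀ is
applied twice, exactly as the physics couples them: as a spectral shift
of every Z-spectrum, and as a PE displacement of every EPI frame via
Δr_pe = Δf_hz·N_pe·ESP (γ in the cycles convention, folded into the
ppm→Hz conversion; the rad/s convention would overstate shifts by 2π).
ESP defaults to 0.5 ms and is always an explicit parameter — it is
rarely printed in methods sections but sets the entire distortion scale.

Forward distortion is a mass-conserving push-forward: each source
pixel's intensity is deposited at y + Δr(y), split linearly between the
two straddling bins.  Converging shifts therefore *sum* (pile-up), and
mass pushed outside the FOV is dropped and reported, not redistributed —
both mirror real EPI.  A `conserve_mass` switch would be a no-op (the
operator conserves by construction), so the API instead exposes the
dropped mass (`return_dropped=True`) with sum(in) = sum(out) + dropped
to ~1e-9 relative.

Noise is Rician (magnitude of two Gaussian quadratures), with σ = mean
in-object M0 / SNR.  Defaults: SNR 40 for the 3 T-like regime, SNR 8
available for a high-field-like low-SNR regime.  Not simulated: 3D/
multi-slice geometry, T₂* blur along readout, eddy currents, motion,
coil-sensitivity profiles.  Passing tests therefore demonstrate the
correctness of the estimation/correction machinery under known ground
truth, not robustness to those real-world effects.

## ΔB₀ by minimum search

Per masked voxel, the Z samples with |Δω| ≤ window (default 1 ppm — the
typical in vivo ΔB₀ range; a config knob for stronger fields) are
interpolated onto a dense grid (default step 0.001 ppm) and the grid
offset minimizing Z is returned.  Ties take the grid point closest to
0 ppm (deterministic, bias-minimal); minima on the window boundary and
flat spectra are flagged invalid, and invalid voxels are excluded from
all statistics and get zero shift (safer than extrapolating shifts into
background).  The default mask is Otsu's threshold on the mean M0 image
(parameter-free, recorded in metadata).

The default interpolant is a **penalized cubic smoothing spline**
(`scipy.interpolate.make_smoothing_spline`, fixed curvature penalty
λ = 1e-3 in ppm units), not an exact interpolating spline.  This is a
bias–variance decision: the exact interpolant reproduces every noise
wiggle, and its minimum is then noise-dominated (≈ 0.04 ppm RMSE at
SNR 40 on the creatine phantom, versus ≈ 0.013 ppm with the default);
because the smoothing is symmetric it does not move the minimum of a
(locally symmetric) DS dip, so the noiseless error stays at the dense-
grid resolution (~5e-4 ppm), and the result is insensitive to λ over at
least a decade.  `interp_kind="cubic"` (exact spline) and `"linear"`
are available for robustness checks.  Parabola or centroid refinements
of the minimum are intentionally not implemented — the estimator stays
plain interpolation + minimum search.

The two-TE comparator computes Δf = wrap(φ₂ − φ₁)/(2π·ΔTE) per pixel;
its unambiguous range is ±1/(2·ΔTE) Hz and no spatial unwrapping is
attempted beyond the single-difference wrap.

## The DISC pass

`run_disc` performs exactly one geometric pass: normalize → estimate
ΔB₀ (in the distorted frame) → shift map → unwarp every frame including
M0 → re-normalize → re-estimate ΔB₀ → per-voxel Z-spectrum correction.
Unwarping is a pull-back with Δr evaluated at the *corrected*
coordinate (the shift estimated in the distorted frame stands in for
the shift at the unknown source location — a first-order scheme), using
1D linear interpolation along PE (cubic optional), fill value 0 outside
the grid.  No Jacobian intensity modulation is applied, so pile-up is
*not* undone: with strongly converging shifts the corrected image
retains a residual, which the test suite asserts as a documented method
boundary rather than hiding.  An optional fixed-point refinement
(`n_refine`) re-estimates the field from the corrected stack and
re-unwarps the raw stack; it is off by default to match the single-pass
design.  M0 frames are unwarped with the same map — normalization
requires M0 and saturated frames in the same geometry.

Z-spectrum correction resamples each voxel's spectrum at Δω + ΔB₀ with
a cubic spline, clips the result to the [min, max] envelope of the
input spectrum (no spline overshoot), flags extrapolated offsets, and
passes field-invalid voxels through untouched.

## Quantification

Normalization uses the mean of the **last two** M0 frames as the
denominator (the first M0 frame is commonly discarded as a dummy for
steady-state reasons; with fewer than two M0 frames all available are
averaged, with a warning).  Voxels with non-positive M₀ are invalidated.
Z is scale-invariant by construction.

The DS reference for inverse-Z analysis is a four-parameter least-
squares fit Z(Δω) ≈ b − A·(Γ²/4)/((Γ²/4)+(Δω−δ)²) over |Δω| ≤ 1.2 ppm
plus |Δω| ≥ 6 ppm — ranges chosen to exclude the creatine, amide and
rNOE bands; they are configurable and recorded.  The baseline is flat
(the minimal model consistent with "a Lorentzian"), which absorbs the
broad MT pool at the cost of a small documented bias where MT is not
flat across the wings.  Fits that fail to converge invalidate the
voxel; widths pinned at a bound are flagged.  Probes not on the sampled
grid are obtained by spline interpolation (the phantom schedule samples
±2 and ±3.5 ppm exactly).  A Z floor of 0.05 guards the 1/Z blow-up in
low-SNR data; such voxels are flagged, never silently clipped.

## Evaluation

SSIM uses the standard 11×11 Gaussian window (σ = 1.5), k₁ = 0.01,
k₂ = 0.03, L = dynamic range (default: the reference's maximum — pass L
explicitly for a symmetric score).  The reported value averages the
local SSIM map over an explicit mask, defaulting to the interior that
excludes the half-window border where local statistics touch padding;
with that mask the implementation agrees with
`skimage.metrics.structural_similarity` to ~1e-7 and with a brute-force
per-pixel evaluation to 1e-8.  Dataset SSIM is the unweighted mean over
frames.  ROI agreement uses Pearson correlation of paired ROI means
(n ≥ 3, zero-variance inputs rejected); group comparisons use the
paired two-sided t-test, with an exact sign-flip permutation variant
(all 2ⁿ flips, n ≤ 12) as the distribution-free cross-check.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use the 96×96 phantom
with the full 106-frame (phantom) and 76-frame (in vivo-style)
schedules; the correction-benefit study uses 20 noise realizations at
SNR 40, which completes in about two minutes on one CPU.  Unit tests
use 32–48 px grids for speed; all sizes are parameters, not limits.

## Known limitations

- Lorentzian superposition, not Bloch–McConnell: no power/duration
  dependence; amplitudes are phenomenological.
- One-pass pull-back correction: first-order in the shift, no Jacobian
  modulation, pile-up not recoverable (by design, asserted in tests).
- Flat DS-fit baseline biases CEST_rex slightly when MT is strong.
- No spatial phase unwrapping in the two-TE map; fields beyond
  ±1/(2ΔTE) alias.
- 2D single-slice only; no motion, relaxation or coil effects in the
  simulator.
- Plot generation is out of scope; reports are JSON/CSV and images are
  NIfTI.
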