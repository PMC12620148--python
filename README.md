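# cestdisc

Distortion **self**-correction (DISC) and quantification for single-shot
CEST-EPI, with a digital-phantom simulator that makes the whole pipeline
testable without scanner data.

## The problem

Chemical exchange saturation transfer (CEST) MRI sweeps a saturation
pulse across frequency offsets Δω and images the water signal after each
one, giving a per-voxel Z-spectrum Z(Δω) = M_sat(Δω)/M₀.  Single-shot
EPI is the fast readout of choice for these long sweeps, but B₀
inhomogeneity displaces EPI signal along the phase-encode (PE) direction
by

    Δr_pe = γ · ΔB₀ · N_pe · ESP     [pixels]

(γ·ΔB₀ the off-resonance in Hz, N_pe the PE matrix size, ESP the
effective echo spacing), so the images are geometrically warped wherever
the field is off.

The same ΔB₀ also shifts each voxel's Z-spectrum: its direct-water-
saturation (DS) minimum sits at the local water frequency.  The CEST
sweep therefore *already contains a field map*.  DISC exploits this:

1. estimate ΔB₀ per voxel by interpolation + minimum search of its
   Z-spectrum,
2. convert it to a pixel-shift map and unwarp every frame
   (`corrected(y) = distorted(y + Δr_pe(y))`, including the M0 frames),
3. re-estimate ΔB₀ from the corrected data, and
4. shift each spectrum back onto the water resonance (Z-spectrum
   correction) before quantification.

No extra acquisition is needed.  Quantification supports asymmetry
analysis, MTRasym(Δω) = Z(−Δω) − Z(+Δω), and inverse-Z contrasts,
CEST_rex = 1/Z(Δω) − 1/Z_ref(Δω) with Z_ref a Lorentzian DS fit, for
APT (+3.5 ppm) and rNOE (−3.5 ppm) mapping.  A two-echo GRE field-map
comparator (Δf = Δφ/(2π·ΔTE)) and SSIM/correlation evaluation tools are
included.

## Worked example

```bash
cestdisc all --preset creatine3t --seed 1 --snr 40 --out run/
```

simulates a seven-tube creatine phantom (96×96, 106-frame sweep, smooth
ΔB₀ field, Rician noise at SNR 40), runs DISC, and prints

```
SSIM before=0.4711 after=0.4867 -> run/run_report.json
```

— the whole-dataset structural similarity against the noiseless ground
truth before and after correction.  `run/run_report.json` additionally
records the ΔB₀ estimation error (`b0_rmse_initial_ppm` ≈ 0.013 ppm at
this SNR) and the run configuration; `run/` holds the corrected stack,
the DISC ΔB₀ map and the creatine MTRasym map as NIfTI.

The same stages are available individually (`cestdisc simulate`,
`b0map`, `disc`, `quant`, `eval`) and as library functions:

```python
import cestdisc as cd

spec = cd.make_creatine_phantom(seed=1, snr=40.0)
epi, rare, truth = cd.simulate_dataset(spec)
result = cd.run_disc(epi)                       # unwarp + Z-spectrum correction
cm = cd.mtr_asym_map(result.corrected, 2.0)     # creatine CEST map
```

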