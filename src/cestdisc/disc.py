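"""Distortion self-correction (DISC) for single-shot CEST-EPI.

B₀ inhomogeneity displaces single-shot EPI signal along the phase-encode
(PE) axis by

    Δr_pe = Δf · N_pe · ESP        [pixels],  Δf = ΔB₀(ppm) · f0(MHz)  [Hz]

(γ in the cycles convention is folded into the ppm→Hz conversion).  A pixel
observed at ``y_dist`` in the distorted image originated at
``y = y_dist − Δr_pe``; equivalently the corrected image is the pull-back
``corrected(y) = distorted(y + Δr_pe(y))``.

Because the same ΔB₀ also shifts each voxel's Z-spectrum, the CEST sweep
itself carries the field map: estimate ΔB₀ from the spectra, unwarp every
frame, re-estimate ΔB₀ from the corrected data, and finally shift each
spectrum back onto the water resonance (Z-spectrum correction, ZC).  That
whole loop — no extra acquisition — is :func:`run_disc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .b0map import FieldMap, estimate_b0_minsearch, otsu_mask
from .protocol import ReadoutParams, SaturationSchedule

logger = logging.getLogger(__name__)


@dataclass
class ShiftMap:
    """Per-pixel signed displacement along PE, in pixels."""

    shift_px: np.ndarray
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift_px = np.asarray(self.shift_px, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not np.all(np.isfinite(self.shift_px[self.valid_mask])):
            raise ValueError("non-finite shift at a valid pixel")
        self.shift_px = np.where(self.valid_mask, self.shift_px, 0.0)


@dataclass
class CestStack:
    """A 2D image plane per saturation frame: ``data[x, y, frame]``.

    Axis 0 is frequency encode (x), axis 1 phase encode (y).  A raw stack
    contains M0 frames at the positions flagged by the schedule; a
    normalized stack holds Z values with M0 frames removed, frames ordered
    by ascending offset.
    """

    data: np.ndarray
    schedule: SaturationSchedule
    readout: Optional[ReadoutParams] = None
    normalized: bool = False
    valid_mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (nx, ny, n_frames)")
        expected = self.schedule.n_offsets if self.normalized else self.schedule.n_frames
        if self.data.shape[2] != expected:
            raise ValueError(
                f"frame count {self.data.shape[2]} does not match schedule ({expected})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def offsets_ppm(self) -> np.ndarray:
        return np.asarray(self.schedule.offsets_ppm)

    def m0_image(self) -> np.ndarray:
        """Mean image over the M0 frames (raw) or all-frames mean (normalized)."""
        if self.normalized:
            return self.data.mean(axis=2)
        return self.data[..., self.schedule.m0_frame_indices].mean(axis=2)


def compute_shift_map(field_map: FieldMap, readout: ReadoutParams) -> ShiftMap:
    """Convert a ΔB₀ map into a PE pixel-shift map.

    ``Δr_pe = pe_polarity · Δf_hz · n_pe · esp_s`` — linear in the field,
    the PE matrix size, and the echo spacing.  Field-invalid pixels get
    shift 0 and stay flagged.
    """
    if readout.modality != "EPI":
        raise ValueError("pixel shifts apply to EPI readouts only")
    if readout.esp_s is None:
        raise ValueError("readout.esp_s is required to compute pixel shifts")
    shift = readout.pe_polarity * field_map.delta_f_hz * readout.n_pe * readout.esp_s
    return ShiftMap(
        shift_px=shift,
        valid_mask=field_map.valid_mask.copy(),
        provenance={
            "f0_mhz": field_map.f0_mhz,
            "n_pe": readout.n_pe,
            "esp_s": readout.esp_s,
            "pe_polarity": readout.pe_polarity,
            "field_method": field_map.meta.get("method"),
        },
    )


def unwarp_frame(
    frame: np.ndarray,
    shift: ShiftMap,
    interp_kind: str = "linear",
    fill_value: float = 0.0,
) -> np.ndarray:
    """Undo the PE displacement of one frame by pull-back resampling.

    ``corrected[x, y] = frame[x, y + shift[x, y]]`` with 1D interpolation
    along each PE column; sample positions outside the grid take
    ``fill_value``.  Pile-up (several true locations collapsed into one
    distorted pixel) is *not* invertible by this resampling and remains as
    residual error wherever shifts converge strongly.
    """
    img = np.asarray(frame, dtype=float)
    if img.shape != shift.shift_px.shape:
        raise ValueError("frame and shift map shapes differ")
    nx, ny = img.shape
    ys = np.arange(ny, dtype=float)
    pos = ys[None, :] + shift.shift_px  # sampling positions in the distorted frame
    if interp_kind == "linear":
        lo = np.clip(np.floor(pos).astype(int), 0, ny - 2)
        inside = (pos >= 0.0) & (pos <= ny - 1.0)
        rows = np.arange(nx)[:, None]
        a = img[rows, lo]
        b = img[rows, lo + 1]
        out = a + (pos - lo) * (b - a)
        out = np.where(inside, out, fill_value)
    elif interp_kind == "cubic":
        out = np.empty_like(img)
        for i in range(nx):
            cs = CubicSpline(ys, img[i], extrapolate=False)
            v = cs(pos[i])
            out[i] = np.where(np.isnan(v), fill_value, v)
    else:
        raise ValueError(f"unknown interp_kind {interp_kind!r}")
    return out


def unwarp_stack(stack: CestStack, shift: ShiftMap, interp_kind: str = "linear") -> CestStack:
    """Apply :func:`unwarp_frame` to every frame (M0 frames included)."""
    out = np.empty_like(stack.data)
    for f in range(stack.data.shape[2]):
        out[..., f] = unwarp_frame(stack.data[..., f], shift, interp_kind=interp_kind)
    return replace(stack, data=out)


def correct_zspectrum(
    z: np.ndarray,
    offsets_ppm: np.ndarray,
    delta_b0_ppm: float,
    return_flags: bool = False,
):
    """Shift one Z-spectrum back onto the water resonance.

    ``corrected(Δω) = Z(Δω + ΔB₀)`` via cubic spline; the corrected values
    are clipped to the [min, max] envelope of the input (no spline
    overshoot), and offsets that required extrapolation are flagged.
    """
    z = np.asarray(z, dtype=float)
    offsets = np.asarray(offsets_ppm, dtype=float)
    if not np.isfinite(delta_b0_ppm):
        out = np.full_like(z, np.nan)
        return (out, np.ones(z.shape, bool)) if return_flags else out
    if delta_b0_ppm == 0.0:
        return (z.copy(), np.zeros(z.shape, bool)) if return_flags else z.copy()
    pos = offsets + delta_b0_ppm
    cs = CubicSpline(offsets, z, axis=-1)
    out = np.clip(cs(pos), z.min(axis=-1, keepdims=True), z.max(axis=-1, keepdims=True))
    extrapolated = (pos < offsets[0]) | (pos > offsets[-1])
    return (out, extrapolated) if return_flags else out


def correct_stack_zspectra(stack: CestStack, field_map: FieldMap) -> CestStack:
    """Per-voxel Z-spectrum correction of a normalized stack.

    Field-invalid voxels pass through uncorrected.
    """
    if not stack.normalized:
        raise ValueError("Z-spectrum correction expects a normalized stack")
    offsets = stack.offsets_ppm
    nx, ny, nf = stack.data.shape
    z = stack.data.reshape(-1, nf)
    b0 = field_map.delta_b0_ppm.ravel()
    valid = field_map.valid_mask.ravel()
    out = z.copy()
    idx = np.flatnonzero(valid & (b0 != 0.0))
    # each voxel samples its own spline at offsets + its own ΔB₀
    for lo in range(0, idx.size, 4096):
        sel = idx[lo : lo + 4096]
        pos = offsets[None, :] + b0[sel, None]
        vals = _eval_splines_rowwise(offsets, z[sel], pos)
        lo_env = z[sel].min(axis=1, keepdims=True)
        hi_env = z[sel].max(axis=1, keepdims=True)
        out[sel] = np.clip(vals, lo_env, hi_env)
    corrected = replace(stack, data=out.reshape(nx, ny, nf))
    return corrected


def _eval_splines_rowwise(x: np.ndarray, y: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Evaluate, for each row i, the cubic spline through (x, y[i]) at pos[i].

    CubicSpline stores coefficients per interval with shape (4, n-1, nrow);
    gathering the interval of each query point makes the evaluation fully
    vectorized over rows.
    """
    cs = CubicSpline(x, y, axis=1)
    c = cs.c  # (4, n_intervals, nrow)
    pos_c = np.clip(pos, x[0], x[-1])
    iv = np.clip(np.searchsorted(x, pos_c, side="right") - 1, 0, x.size - 2)
    rows = np.arange(y.shape[0])[:, None]
    dx = pos_c - x[iv]
    out = np.zeros_like(pos_c)
    for k in range(4):
        out = out * dx + c[k][iv, rows]
    return out


@dataclass
class DiscResult:
    """Everything :func:`run_disc` produces."""

    corrected: CestStack          # normalized + unwarped + Z-spectrum-corrected
    unwarped_raw: CestStack       # raw intensities after geometric correction
    field_initial: FieldMap       # ΔB₀ estimated in the distorted frame
    field_disc: FieldMap          # ΔB₀ re-estimated after unwarping
    shift_map: ShiftMap
    mask: np.ndarray


def run_disc(
    stack: CestStack,
    mask: np.ndarray | None = None,
    window_ppm: float = 1.0,
    grid_step_ppm: float = 0.001,
    interp_kind: str = "linear",
    n_refine: int = 0,
) -> DiscResult:
    """One-pass distortion self-correction of a raw CEST-EPI stack.

    Pipeline: normalize → ΔB₀ by minimum search (distorted frame) →
    pixel-shift map → unwarp every frame including M0 → re-normalize →
    DISC ΔB₀ map → per-voxel Z-spectrum correction.  ``n_refine`` extra
    fixed-point iterations (re-estimate the field from the corrected stack
    and re-unwarp the *raw* stack) are available but off by default, which
    is the single-geometric-pass scheme.
    """
    from .quant import normalize_stack

    if stack.normalized:
        raise ValueError("run_disc expects a raw stack with M0 frames")
    if stack.readout is None or stack.readout.modality != "EPI":
        raise ValueError("run_disc expects an EPI stack with readout parameters")

    norm0 = normalize_stack(stack)
    if mask is None:
        mask = otsu_mask(stack.m0_image())
    field_initial = estimate_b0_minsearch(
        norm0, mask=mask, window_ppm=window_ppm, grid_step_ppm=grid_step_ppm
    )
    shift = compute_shift_map(field_initial, stack.readout)
    unwarped = unwarp_stack(stack, shift, interp_kind=interp_kind)

    for _ in range(n_refine):
        norm_i = normalize_stack(unwarped)
        mask_i = otsu_mask(unwarped.m0_image())
        field_i = estimate_b0_minsearch(
            norm_i, mask=mask_i, window_ppm=window_ppm, grid_step_ppm=grid_step_ppm
        )
        shift = compute_shift_map(field_i, stack.readout)
        unwarped = unwarp_stack(stack, shift, interp_kind=interp_kind)

    mask_disc = otsu_mask(unwarped.m0_image())
    norm1 = normalize_stack(unwarped)
    field_disc = estimate_b0_minsearch(
        norm1, mask=mask_disc, window_ppm=window_ppm, grid_step_ppm=grid_step_ppm
    )
    corrected = correct_stack_zspectra(norm1, field_disc)
    logger.info(
        "DISC: %d masked voxels, %d invalid in initial field, %d in DISC field",
        int(mask.sum()),
        field_initial.meta.get("n_invalid", -1),
        field_disc.meta.get("n_invalid", -1),
    )
    return DiscResult(
        corrected=corrected,
        unwarped_raw=unwarped,
        field_initial=field_initial,
        field_disc=field_disc,
        shift_map=shift,
        mask=mask,
    )
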