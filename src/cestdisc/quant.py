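"""CEST quantification: normalization, MTRasym, and inverse-Z contrasts.

Normalization divides each saturated frame by the unsaturated reference
M₀ (mean of the *last two* M0 frames): Z(Δω) = M_sat(Δω)/M₀.

Two contrast conventions are supported:

* asymmetry analysis, MTRasym(Δω) = Z(−Δω) − Z(+Δω), the standard for a
  single exchangeable pool such as creatine amine at 2 ppm;
* inverse-Z analysis, CEST_rex(Δω) = 1/Z(Δω) − 1/Z_ref(Δω), where Z_ref
  is a Lorentzian fit to the direct-water-saturation (DS) dip — used for
  amide (+3.5 ppm, APT) and rNOE (−3.5 ppm) in tissue, where asymmetry is
  confounded by MT and rNOE on the opposite side of water.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

from .disc import CestStack

logger = logging.getLogger(__name__)

#: Z floor guarding the 1/Z blow-up in the low-SNR regime
Z_FLOOR = 0.05

#: default DS-fit offset ranges: around water plus the far wings, skipping
#: the amide/rNOE/creatine bands
DS_FIT_RANGES_PPM = ((-1.2, 1.2), (-np.inf, -6.0), (6.0, np.inf))


@dataclass
class ZSpectrum:
    """One voxel's normalized spectrum."""

    offsets_ppm: np.ndarray
    z_values: np.ndarray
    voxel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.offsets_ppm.shape != self.z_values.shape:
            raise ValueError("offsets and z shapes differ")


@dataclass
class ContrastMap:
    values: np.ndarray
    kind: str                     # e.g. "MTRasym@2.0", "APT(+3.5)", "rNOE(-3.5)"
    mask: np.ndarray

    def roi_means(self, label_map: np.ndarray, labels: Sequence[str]) -> dict[str, float]:
        out = {}
        for i, lab in enumerate(labels):
            sel = (label_map == i) & self.mask
            out[lab] = float(self.values[sel].mean()) if sel.any() else float("nan")
        return out


@dataclass
class DsFit:
    """Fitted DS Lorentzian + flat baseline: Z_ref(Δω) = b − A·L(Δω; Γ, δ)."""

    amplitude: float
    width_ppm: float
    center_ppm: float
    baseline: float
    converged: bool = True
    at_bounds: bool = False

    def z_ref(self, offsets_ppm) -> np.ndarray:
        x = np.asarray(offsets_ppm, dtype=float)
        g2 = self.width_ppm**2 / 4.0
        return self.baseline - self.amplitude * g2 / (g2 + (x - self.center_ppm) ** 2)


def normalize_stack(raw: CestStack) -> CestStack:
    """Z-spectrum normalization per voxel: divide by the mean of the last
    two M0 frames, drop M0 frames, order the rest by ascending offset.

    Voxels with non-positive M₀ are flagged invalid (mask on the returned
    stack) and carry Z = 0.
    """
    if raw.normalized:
        raise ValueError("stack is already normalized")
    m0_idx = raw.schedule.m0_frame_indices
    if raw.schedule.n_m0 >= 2:
        m0 = raw.data[..., m0_idx[-2:]].mean(axis=2)
    else:
        warnings.warn("fewer than 2 M0 frames; averaging all available", stacklevel=2)
        m0 = raw.data[..., m0_idx].mean(axis=2)
    valid = m0 > 0
    sat = raw.data[..., raw.schedule.offset_frame_indices]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(valid[..., None], sat / m0[..., None], 0.0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("normalize_stack: %d voxels with non-positive M0 masked", n_bad)
    return replace(raw, data=z, normalized=True, valid_mask=valid)


def _interp_z(offsets: np.ndarray, z: np.ndarray, at: float) -> np.ndarray:
    """Spline-interpolated Z at an arbitrary probe offset (exact when the
    probe is a sampled offset); works on (..., n_offsets) arrays."""
    hit = np.isclose(offsets, at, atol=1e-9)
    if hit.any():
        return z[..., int(np.argmax(hit))]
    cs = CubicSpline(offsets, z, axis=-1)
    return cs(at)


def mtr_asym(z: ZSpectrum, probe_ppm: float = 2.0) -> float:
    """Asymmetry at a probe offset: Z(−probe) − Z(+probe)."""
    lo, hi = z.offsets_ppm[0], z.offsets_ppm[-1]
    if not (lo <= -abs(probe_ppm) and abs(probe_ppm) <= hi):
        raise ValueError(f"probe ±{probe_ppm} ppm outside sampled range [{lo}, {hi}]")
    return float(
        _interp_z(z.offsets_ppm, z.z_values, -probe_ppm)
        - _interp_z(z.offsets_ppm, z.z_values, probe_ppm)
    )


def mtr_asym_map(stack: CestStack, probe_ppm: float = 2.0, mask: np.ndarray | None = None) -> ContrastMap:
    """MTRasym map of a normalized stack."""
    if not stack.normalized:
        raise ValueError("mtr_asym_map expects a normalized stack")
    offsets = stack.offsets_ppm
    lo, hi = offsets[0], offsets[-1]
    if not (lo <= -abs(probe_ppm) and abs(probe_ppm) <= hi):
        raise ValueError(f"probe ±{probe_ppm} ppm outside sampled range [{lo}, {hi}]")
    vals = _interp_z(offsets, stack.data, -probe_ppm) - _interp_z(offsets, stack.data, probe_ppm)
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    if stack.valid_mask is not None:
        mask = mask & stack.valid_mask
    return ContrastMap(values=vals, kind=f"MTRasym@{probe_ppm:g}", mask=mask)


def _ds_model(x, a, g, d, b):
    g2 = g * g / 4.0
    return b - a * g2 / (g2 + (x - d) ** 2)


def fit_ds_lorentzian(
    z: ZSpectrum,
    fit_ranges_ppm: Sequence[tuple[float, float]] = DS_FIT_RANGES_PPM,
) -> DsFit:
    """Least-squares Lorentzian fit of the direct-water-saturation dip.

    Fitting is restricted to offsets inside ``fit_ranges_ppm`` (default:
    |Δω| ≤ 1.2 ppm plus the |Δω| ≥ 6 ppm wings) so solute pools do not
    bias the reference.  Returns the pool, a flat baseline, and flags for
    non-convergence or a width pinned at its bound.
    """
    x, y = z.offsets_ppm, z.z_values
    sel = np.zeros(x.shape, dtype=bool)
    for lo, hi in fit_ranges_ppm:
        sel |= (x >= lo) & (x <= hi)
    if sel.sum() < 6:
        raise ValueError(f"only {int(sel.sum())} points inside the DS fit ranges; need >= 6")
    xs, ys = x[sel], y[sel]
    a0 = float(np.clip(ys.max() - ys.min(), 1e-3, 1.0))
    d0 = float(xs[np.argmin(ys)])
    p0 = (a0, 1.5, np.clip(d0, -1.0, 1.0), float(ys.max()))
    bounds = ([0.0, 0.05, -2.0, 0.0], [1.5, 20.0, 2.0, 2.0])
    try:
        popt, _ = curve_fit(_ds_model, xs, ys, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError:
        return DsFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    a, g, d, b = (float(v) for v in popt)
    at_bounds = bool(np.isclose(g, bounds[0][1]) or np.isclose(g, bounds[1][1]))
    return DsFit(a, g, d, b, converged=True, at_bounds=at_bounds)


def cest_rex(z_value: float, z_ref_value: float) -> float:
    """Inverse-Z contrast of one voxel at one probe: 1/Z − 1/Z_ref."""
    if z_value < Z_FLOOR or z_ref_value < Z_FLOOR:
        return float("nan")
    return 1.0 / z_value - 1.0 / z_ref_value


def cest_rex_map(
    stack: CestStack,
    probe_ppm: float,
    mask: np.ndarray | None = None,
    fit_ranges_ppm: Sequence[tuple[float, float]] = DS_FIT_RANGES_PPM,
    z_floor: float = Z_FLOOR,
) -> ContrastMap:
    """Inverse-Z contrast map at a probe offset (+3.5 → APT, −3.5 → rNOE).

    Per masked voxel the DS reference is fitted independently, then
    CEST_rex = 1/Z(probe) − 1/Z_ref(probe).  Voxels with Z below
    ``z_floor``, a failed fit, or an invalid normalization are excluded.
    """
    if not stack.normalized:
        raise ValueError("cest_rex_map expects a normalized stack")
    offsets = stack.offsets_ppm
    nx, ny, _ = stack.data.shape
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    if stack.valid_mask is not None:
        mask = mask & stack.valid_mask
    kind = f"APT(+{probe_ppm:g})" if probe_ppm > 0 else f"rNOE({probe_ppm:g})"
    values = np.full((nx, ny), np.nan)
    out_mask = np.zeros((nx, ny), dtype=bool)
    z_probe_all = _interp_z(offsets, stack.data, probe_ppm)
    n_fail = 0
    for i, j in zip(*np.nonzero(mask)):
        fit = fit_ds_lorentzian(ZSpectrum(offsets, stack.data[i, j]), fit_ranges_ppm)
        if not fit.converged:
            n_fail += 1
            continue
        zp = float(z_probe_all[i, j])
        zr = float(fit.z_ref(probe_ppm))
        if zp < z_floor or zr < z_floor:
            continue
        values[i, j] = 1.0 / zp - 1.0 / zr
        out_mask[i, j] = True
    if n_fail:
        logger.info("cest_rex_map(%s): DS fit failed at %d voxels", kind, n_fail)
    return ContrastMap(values=values, kind=kind, mask=out_mask)
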