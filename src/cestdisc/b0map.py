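"""Per-voxel static-field (ΔB₀) mapping.

Two estimators are provided:

* :func:`estimate_b0_minsearch` — the Z-spectrum route: the direct-water-
  saturation dip is centred at the local water frequency, so the offset
  minimising the interpolated Z-spectrum *is* the voxel's ΔB₀.  This needs
  no extra acquisition — the CEST sweep itself is the field map source.
* :func:`field_map_two_te` — the classical comparator: phase difference of
  two gradient-echo images at different echo times, Δf = Δφ/(2π·ΔTE).

ΔB₀ is carried in ppm together with the scanner reference frequency
``f0_mhz`` (γ·B₀ for ¹H), so conversion to Hz is just multiplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import CubicSpline, interp1d, make_smoothing_spline

if TYPE_CHECKING:  # pragma: no cover
    from .disc import CestStack
    from .protocol import SaturationSchedule

logger = logging.getLogger(__name__)

#: ¹H gyromagnetic ratio in MHz/T (cycles convention)
GAMMA_MHZ_PER_T = 42.577


def ppm_to_hz(value_ppm, f0_mhz: float):
    """Frequency offset in Hz for a chemical-shift offset in ppm at
    reference frequency ``f0_mhz`` (1 ppm of 127.7 MHz is 127.7 Hz)."""
    return np.asarray(value_ppm, dtype=float) * f0_mhz


def hz_to_ppm(value_hz, f0_mhz: float):
    if f0_mhz == 0:
        raise ValueError("f0_mhz must be nonzero")
    return np.asarray(value_hz, dtype=float) / f0_mhz


@dataclass
class FieldMap:
    """Per-pixel ΔB₀ in ppm with a validity mask.

    Invalid pixels hold 0.0 and are excluded from statistics; ``f0_mhz``
    fixes the ppm↔Hz conversion.
    """

    delta_b0_ppm: np.ndarray
    valid_mask: np.ndarray
    f0_mhz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_b0_ppm = np.asarray(self.delta_b0_ppm, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.delta_b0_ppm.shape != self.valid_mask.shape:
            raise ValueError("field and mask shapes differ")
        self.delta_b0_ppm = np.where(self.valid_mask, self.delta_b0_ppm, 0.0)

    @property
    def delta_f_hz(self) -> np.ndarray:
        return ppm_to_hz(self.delta_b0_ppm, self.f0_mhz)

    def rmse_vs(self, truth_ppm: np.ndarray, mask: np.ndarray | None = None) -> float:
        """Root-mean-square error against a reference map over valid pixels."""
        m = self.valid_mask if mask is None else (self.valid_mask & mask)
        if not m.any():
            return float("nan")
        d = self.delta_b0_ppm[m] - np.asarray(truth_ppm, dtype=float)[m]
        return float(np.sqrt(np.mean(d * d)))


def otsu_mask(m0_image: np.ndarray) -> np.ndarray:
    """Foreground mask from Otsu's threshold on a mean-M0 image."""
    from skimage.filters import threshold_otsu

    img = np.asarray(m0_image, dtype=float)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def estimate_b0_minsearch(
    stack: "CestStack | np.ndarray",
    schedule: "SaturationSchedule | None" = None,
    mask: np.ndarray | None = None,
    window_ppm: float = 1.0,
    grid_step_ppm: float = 0.001,
    interp_kind: str = "smoothing",
    smoothing_lam: float = 1e-3,
    f0_mhz: float | None = None,
) -> FieldMap:
    """ΔB₀ map by interpolation + minimum search of each voxel's Z-spectrum.

    Per masked voxel the in-window Z samples are interpolated onto a dense
    grid over ``[-window, +window]`` and the grid offset minimising Z is
    returned.  Ties pick the grid point closest to 0 ppm.  Voxels whose
    minimum sits on the window boundary, and voxels with a flat
    (degenerate) spectrum, are flagged invalid.

    The default interpolant is a penalized cubic smoothing spline
    (``smoothing_lam`` is the curvature-penalty weight in ppm units): the
    exact interpolant's minimum chases noise wiggles on noisy spectra,
    while a mild symmetric smoothing leaves the dip center essentially
    unbiased.  ``interp_kind='cubic'`` gives the exact interpolating
    spline and ``'linear'`` piecewise-linear, for robustness checks.

    ``stack`` may be a normalized :class:`~cestdisc.disc.CestStack` or a
    raw ``(nx, ny, n_offsets)`` Z array with ``schedule`` supplied.
    """
    from .disc import CestStack  # local import to avoid cycle

    if isinstance(stack, CestStack):
        if not stack.normalized:
            raise ValueError("estimate_b0_minsearch expects a normalized stack")
        data = stack.data
        schedule = stack.schedule
        if f0_mhz is None and stack.readout is not None:
            f0_mhz = stack.readout.f0_mhz
    else:
        data = np.asarray(stack, dtype=float)
        if schedule is None:
            raise ValueError("schedule required when passing a bare array")
    if f0_mhz is None:
        f0_mhz = 127.7

    offsets = np.asarray(schedule.offsets_ppm, dtype=float)
    if np.any(np.diff(offsets) <= 0):
        raise ValueError("offsets must be strictly increasing")
    in_win = np.abs(offsets) <= window_ppm + 1e-12
    if in_win.sum() < 4:
        raise ValueError(
            f"need at least 4 saturation offsets inside ±{window_ppm} ppm, "
            f"got {int(in_win.sum())}"
        )
    x = offsets[in_win]
    if grid_step_ppm > np.max(np.diff(x)):
        raise ValueError("grid_step_ppm coarser than the in-window sampling")

    nx, ny = data.shape[:2]
    if mask is None:
        mask = np.ones((nx, ny), dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    n_grid = int(round(2 * window_ppm / grid_step_ppm)) + 1
    grid = np.linspace(-window_ppm, window_ppm, n_grid)
    # evaluate grid points in order of |offset| so that argmin's first-hit
    # tie-break selects the candidate closest to 0 ppm
    order = np.argsort(np.abs(grid), kind="stable")
    grid_sorted = grid[order]

    z = data[..., in_win].reshape(-1, x.size)
    flat_idx = np.flatnonzero(mask.ravel())
    est = np.zeros(nx * ny)
    valid = np.zeros(nx * ny, dtype=bool)

    if interp_kind not in ("smoothing", "cubic", "linear"):
        raise ValueError(f"unknown interp_kind {interp_kind!r}")
    chunk = 4096
    for lo in range(0, flat_idx.size, chunk):
        sel = flat_idx[lo : lo + chunk]
        zin = z[sel]  # (nvox, nsamp)
        if interp_kind == "cubic":
            dense = CubicSpline(x, zin, axis=1)(grid_sorted)
        elif interp_kind == "linear":
            dense = interp1d(x, zin, axis=1, kind="linear")(grid_sorted)
        else:
            dense = np.empty((zin.shape[0], grid_sorted.size))
            for v in range(zin.shape[0]):
                dense[v] = make_smoothing_spline(x, zin[v], lam=smoothing_lam)(grid_sorted)
        imin = np.argmin(dense, axis=1)
        cand = grid_sorted[imin]
        span = dense.max(axis=1) - dense.min(axis=1)
        ok = (np.abs(cand) < window_ppm - 1e-12) & (span > 1e-10)
        est[sel] = np.where(ok, cand, 0.0)
        valid[sel] = ok

    n_bad = int(mask.sum() - valid[flat_idx].sum())
    if n_bad:
        logger.info("minimum search: %d of %d masked voxels invalid", n_bad, int(mask.sum()))
    return FieldMap(
        delta_b0_ppm=est.reshape(nx, ny),
        valid_mask=valid.reshape(nx, ny),
        f0_mhz=f0_mhz,
        meta={
            "method": "zspectrum_minsearch",
            "window_ppm": window_ppm,
            "grid_step_ppm": grid_step_ppm,
            "interp_kind": interp_kind,
            "smoothing_lam": smoothing_lam if interp_kind == "smoothing" else None,
            "n_masked": int(mask.sum()),
            "n_invalid": n_bad,
        },
    )


def field_map_two_te(
    phase1: np.ndarray,
    phase2: np.ndarray,
    te1_s: float,
    te2_s: float,
    f0_mhz: float,
    mask: np.ndarray | None = None,
) -> FieldMap:
    """ΔB₀ map from a two-echo gradient-echo phase pair.

    Δf = wrap(φ₂ − φ₁) / (2π·ΔTE), converted to ppm via ``f0_mhz``.  The
    unambiguous range is ±1/(2·ΔTE) Hz; fields outside it alias.
    """
    dte = te2_s - te1_s
    if dte <= 0:
        raise ValueError("te2_s must exceed te1_s")
    dphi = wrap_phase(np.asarray(phase2, float) - np.asarray(phase1, float))
    df_hz = dphi / (2.0 * np.pi * dte)
    valid = np.ones(df_hz.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    return FieldMap(
        delta_b0_ppm=hz_to_ppm(df_hz, f0_mhz),
        valid_mask=valid,
        f0_mhz=f0_mhz,
        meta={
            "method": "two_te_phase",
            "te1_s": te1_s,
            "te2_s": te2_s,
            "range_hz": 0.5 / dte,
        },
    )


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)
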