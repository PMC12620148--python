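"""Digital CEST-EPI phantoms with known ground truth.

Every stage of the correction pipeline is validated by parameter recovery
on synthetic data, so this module is first-class: it builds multi-pool
Lorentzian Z-spectra, a smooth spatial ΔB₀ field that *both* shifts each
voxel's spectrum and displaces pixels along PE, a mass-conserving forward
distortion operator (including the pile-up regime a pull-back cannot
invert), and Rician magnitude noise.

The spectral model is a Lorentzian superposition

    Z(Δω) = 1 − Σᵢ Aᵢ · (Γᵢ²/4) / ((Γᵢ²/4) + (Δω − δᵢ − ΔB₀)²)

— a deliberate approximation to full Bloch–McConnell dynamics, but the
same functional family the quantification stage fits, so recovery tests
are apples-to-apples.

Two recipes mirror the common benchtop and preclinical set-ups: a
seven-tube creatine phantom (2 ppm amine pool, amplitude proportional to
concentration) and an axial "mouse head" with brain/muscle/optional tumor
compartments carrying amide (+3.5 ppm), rNOE (−3.5 ppm) and a broad MT
pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .b0map import FieldMap
from .disc import CestStack, ShiftMap, compute_shift_map
from .protocol import (
    ReadoutParams,
    SaturationSchedule,
    mouse_schedule,
    phantom_3t_schedule,
)


@dataclass(frozen=True)
class LorentzianPool:
    """One saturation pool: peak depth (normalized Z units), FWHM and
    center offset, all in ppm where applicable."""

    amplitude: float
    width_ppm: float
    center_ppm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("pool amplitude must be within [0, 1]")
        if self.width_ppm <= 0:
            raise ValueError("pool width must be positive")


def synth_zspectrum(
    pools: Sequence[LorentzianPool],
    offsets_ppm: np.ndarray,
    delta_b0_ppm: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Z-spectrum of a pool superposition, spectrally shifted by ΔB₀.

    ``delta_b0_ppm`` may be a scalar or an array of per-voxel shifts, in
    which case the result has shape ``shifts.shape + offsets.shape``.
    Values are clipped at 0 from below.
    """
    offs = np.asarray(offsets_ppm, dtype=float)
    b0 = np.asarray(delta_b0_ppm, dtype=float)
    x = offs.reshape((1,) * b0.ndim + offs.shape) - b0[..., None]
    z = np.ones(np.broadcast_shapes(x.shape), dtype=float)
    for p in pools:
        g2 = p.width_ppm**2 / 4.0
        z = z - p.amplitude * g2 / (g2 + (x - p.center_ppm) ** 2)
    return np.clip(z, 0.0, None)


@dataclass(frozen=True)
class Region:
    """One phantom compartment: a geometric mask recipe plus its pools."""

    label: str
    kind: str                      # "disk" | "ellipse" | "annulus"
    center: tuple[float, float]    # pixel coordinates (x, y)
    radii: tuple[float, float]     # semi-axes in pixels (equal for disks)
    pools: tuple[LorentzianPool, ...]
    pd: float = 1.0                # proton-density scale of M0 intensity
    inner_radii: Optional[tuple[float, float]] = None  # annulus hole

    def mask(self, grid: tuple[int, int]) -> np.ndarray:
        nx, ny = grid
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        rx, ry = self.radii
        r2 = ((X - self.center[0]) / rx) ** 2 + ((Y - self.center[1]) / ry) ** 2
        m = r2 <= 1.0
        if self.kind == "annulus":
            irx, iry = self.inner_radii
            ir2 = ((X - self.center[0]) / irx) ** 2 + ((Y - self.center[1]) / iry) ** 2
            m &= ir2 > 1.0
        return m


@dataclass(frozen=True)
class FieldModel:
    """Smooth ΔB₀ surface: low-order 2D polynomial (coordinates normalized
    to [−1, 1]) plus Gaussian bumps, optionally randomly placed."""

    poly_coeffs: tuple[tuple[float, float, float], ...] = ()  # (cx_order, cy_order, coeff ppm)
    bumps: tuple[tuple[float, float, float, float], ...] = ()  # (x_px, y_px, sigma_px, amp_ppm)
    n_random_bumps: int = 0
    random_bump_amp_ppm: float = 0.0
    random_bump_sigma_px: tuple[float, float] = (8.0, 20.0)
    max_abs_ppm: float = 0.5


@dataclass(frozen=True)
class NoiseModel:
    """Rician magnitude noise; ``snr`` is mean in-object M0 over sigma."""

    snr: float = 40.0

    @property
    def enabled(self) -> bool:
        return np.isfinite(self.snr) and self.snr > 0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one synthetic dataset."""

    grid: tuple[int, int]
    regions: tuple[Region, ...]
    field_model: FieldModel
    noise: NoiseModel
    readout: ReadoutParams
    schedule: SaturationSchedule
    seed: int = 0


@dataclass
class GroundTruth:
    """Noiseless, undistorted truth accompanying a simulated dataset."""

    clean_stack: CestStack        # raw intensities, no noise, no distortion
    field: FieldMap               # true ΔB₀ (ppm)
    shift: ShiftMap               # true PE displacement (pixels)
    label_map: np.ndarray         # region index per pixel (−1 = background)
    region_labels: tuple[str, ...]
    region_contrast: dict         # per-region noiseless contrast values


# -- recipes --------------------------------------------------------------

CREATINE_CONCENTRATIONS_MM = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)

#: creatine amine-pool peak depth per mM at ~0.8 µT CW saturation, 3 T
CREATINE_AMP_PER_MM = 0.002

# DI-water phantom at ~0.8 µT CW: the direct-saturation dip is dominated by
# saturation broadening (≈ 2·γ·B1 ≈ 0.5 ppm at 3 T) on a long-T2 background,
# so the effective FWHM is ~1 ppm — far narrower than in tissue
DS_PHANTOM = LorentzianPool(amplitude=0.92, width_ppm=1.0, center_ppm=0.0)
DS_BRAIN = LorentzianPool(amplitude=0.85, width_ppm=1.4, center_ppm=0.0)
MT_POOL = LorentzianPool(amplitude=0.10, width_ppm=25.0, center_ppm=0.0)


def default_epi_readout(f0_mhz: float = 127.7, n_pe: int = 96, n_fe: int = 96) -> ReadoutParams:
    return ReadoutParams(
        modality="EPI", tr_s=6.0, te_s=0.043, n_pe=n_pe, n_fe=n_fe,
        esp_s=0.0005, pe_polarity=+1, fov_mm=35.0, f0_mhz=f0_mhz,
    )


def default_rare_readout(f0_mhz: float = 127.7, n_pe: int = 96, n_fe: int = 96) -> ReadoutParams:
    return ReadoutParams(
        modality="RARE", tr_s=6.0, te_s=0.043, n_pe=n_pe, n_fe=n_fe,
        rare_factor=24, fov_mm=35.0, f0_mhz=f0_mhz,
    )


def make_creatine_phantom(
    grid: tuple[int, int] = (96, 96),
    concentrations_mm: Sequence[float] = CREATINE_CONCENTRATIONS_MM,
    snr: float = 40.0,
    field_model: FieldModel | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """Seven-tube creatine phantom: six tubes with a 2 ppm pool whose
    amplitude is proportional to concentration, plus one water-only tube,
    arranged as a ring of disks."""
    nx, ny = grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ring_r = 0.30 * min(nx, ny)
    disk_r = 0.105 * min(nx, ny)
    regions = []
    # water tube in the middle, creatine tubes around it
    regions.append(
        Region("water", "disk", (cx, cy), (disk_r, disk_r), (DS_PHANTOM,), pd=1.0)
    )
    for i, conc in enumerate(concentrations_mm):
        ang = 2.0 * np.pi * i / len(concentrations_mm)
        c = (cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang))
        cr_pool = LorentzianPool(
            amplitude=CREATINE_AMP_PER_MM * conc, width_ppm=1.0, center_ppm=2.0
        )
        regions.append(
            Region(f"cr{int(conc)}mM", "disk", c, (disk_r, disk_r), (DS_PHANTOM, cr_pool))
        )
    if field_model is None:
        field_model = FieldModel(
            poly_coeffs=((1, 0, 0.10), (0, 1, -0.08), (1, 1, 0.06)),
            n_random_bumps=2,
            random_bump_amp_ppm=0.25,
            max_abs_ppm=0.5,
        )
    return PhantomSpec(
        grid=grid,
        regions=tuple(regions),
        field_model=field_model,
        noise=NoiseModel(snr=snr),
        readout=default_epi_readout(n_pe=grid[1], n_fe=grid[0]),
        schedule=phantom_3t_schedule(),
        seed=seed,
    )


def make_brain_phantom(
    grid: tuple[int, int] = (96, 96),
    with_tumor: bool = False,
    snr: float = 40.0,
    field_model: FieldModel | None = None,
    f0_mhz: float = 127.7,
    seed: int = 0,
) -> PhantomSpec:
    """Axial mouse-head phantom: elliptical brain inside a muscle ring.

    Brain carries DS + amide (+3.5 ppm) + rNOE (−3.5 ppm) + broad MT; the
    optional tumor disk has reduced amide and rNOE amplitudes so both
    contrasts are hypointense relative to contralateral tissue.
    """
    nx, ny = grid
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    amide = LorentzianPool(0.045, 1.5, 3.5)
    rnoe = LorentzianPool(0.060, 3.0, -3.5)
    brain_pools = (DS_BRAIN, amide, rnoe, MT_POOL)
    muscle_pools = (
        LorentzianPool(0.88, 1.5, 0.0),
        LorentzianPool(0.020, 1.5, 3.5),
        LorentzianPool(0.030, 3.0, -3.5),
        LorentzianPool(0.12, 25.0, 0.0),
    )
    regions = [
        Region(
            "muscle", "annulus", (cx, cy),
            (0.46 * nx, 0.42 * ny), muscle_pools, pd=0.9,
            inner_radii=(0.34 * nx, 0.30 * ny),
        ),
        Region("brain", "ellipse", (cx, cy), (0.34 * nx, 0.30 * ny), brain_pools, pd=1.0),
    ]
    if with_tumor:
        tum_amide = LorentzianPool(0.025, 1.5, 3.5)
        tum_rnoe = LorentzianPool(0.035, 3.0, -3.5)
        regions.append(
            Region(
                "tumor", "disk", (cx + 0.15 * nx, cy + 0.10 * ny),
                (0.09 * nx, 0.09 * ny),
                (DS_BRAIN, tum_amide, tum_rnoe, MT_POOL), pd=1.0,
            )
        )
    if field_model is None:
        field_model = FieldModel(
            poly_coeffs=((1, 0, -0.10), (0, 1, 0.12), (2, 0, 0.08)),
            n_random_bumps=2,
            random_bump_amp_ppm=0.25,
            max_abs_ppm=0.5,
        )
    return PhantomSpec(
        grid=grid,
        regions=tuple(regions),
        field_model=field_model,
        noise=NoiseModel(snr=snr),
        readout=default_epi_readout(f0_mhz=f0_mhz, n_pe=grid[1], n_fe=grid[0]),
        schedule=mouse_schedule(),
        seed=seed,
    )


# -- field ----------------------------------------------------------------


def make_field(
    field_model: FieldModel,
    grid: tuple[int, int],
    seed: int | None = None,
    f0_mhz: float = 127.7,
) -> FieldMap:
    """Realize a smooth ΔB₀ map (ppm) from a :class:`FieldModel`.

    Deterministic for a given (model, seed) pair; raises if the realized
    map exceeds the model's ``max_abs_ppm`` bound.
    """
    nx, ny = grid
    xn = np.linspace(-1.0, 1.0, nx)[:, None]
    yn = np.linspace(-1.0, 1.0, ny)[None, :]
    b0 = np.zeros((nx, ny))
    for ox, oy, coeff in field_model.poly_coeffs:
        b0 += coeff * xn**ox * yn**oy
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for bx, by, sig, amp in field_model.bumps:
        b0 += amp * np.exp(-((X - bx) ** 2 + (Y - by) ** 2) / (2.0 * sig**2))
    if field_model.n_random_bumps:
        rng = np.random.default_rng(seed)
        for _ in range(field_model.n_random_bumps):
            bx = rng.uniform(0.2 * nx, 0.8 * nx)
            by = rng.uniform(0.2 * ny, 0.8 * ny)
            sig = rng.uniform(*field_model.random_bump_sigma_px)
            amp = rng.uniform(-1.0, 1.0) * field_model.random_bump_amp_ppm
            b0 += amp * np.exp(-((X - bx) ** 2 + (Y - by) ** 2) / (2.0 * sig**2))
    if np.max(np.abs(b0)) > field_model.max_abs_ppm:
        raise ValueError(
            f"realized field peak {np.max(np.abs(b0)):.3f} ppm exceeds the "
            f"model bound {field_model.max_abs_ppm} ppm"
        )
    return FieldMap(
        delta_b0_ppm=b0,
        valid_mask=np.ones((nx, ny), dtype=bool),
        f0_mhz=f0_mhz,
        meta={"method": "synthetic", "seed": seed},
    )


# -- forward distortion ---------------------------------------------------


def forward_distort(
    image: np.ndarray,
    shift_px: np.ndarray | ShiftMap,
    return_dropped: bool = False,
):
    """Mass-conserving push-forward of an image along PE.

    Each source pixel's intensity is deposited at ``y + Δr(x, y)``, split
    linearly between the two straddling integer bins, so converging shifts
    *sum* (pile-up) exactly as a long-readout EPI acquisition accumulates
    signal.  Mass pushed outside the grid is dropped; its total is
    available via ``return_dropped``.  ``sum(in) = sum(out) + dropped`` to
    floating-point accuracy.
    """
    if isinstance(shift_px, ShiftMap):
        shift_px = shift_px.shift_px
    img = np.asarray(image, dtype=float)
    shift = np.asarray(shift_px, dtype=float)
    if img.shape != shift.shape:
        raise ValueError("image and shift map shapes differ")
    if not np.all(np.isfinite(shift)):
        raise ValueError("non-finite shifts")
    nx, ny = img.shape
    dest = np.arange(ny, dtype=float)[None, :] + shift
    lo = np.floor(dest).astype(int)
    w_hi = dest - lo
    w_lo = 1.0 - w_hi
    out = np.zeros_like(img)
    rows = np.broadcast_to(np.arange(nx)[:, None], img.shape)
    dropped = 0.0
    for bins, w in ((lo, w_lo), (lo + 1, w_hi)):
        inside = (bins >= 0) & (bins < ny)
        np.add.at(out, (rows[inside], bins[inside]), (img * w)[inside])
        dropped += float((img * w)[~inside].sum())
    return (out, dropped) if return_dropped else out


# -- full dataset ---------------------------------------------------------


def _region_assignment(spec: PhantomSpec) -> tuple[np.ndarray, list[Region]]:
    """Label map with later regions overriding earlier ones (tumor inside
    brain inside muscle annulus)."""
    label_map = np.full(spec.grid, -1, dtype=int)
    for i, reg in enumerate(spec.regions):
        label_map[reg.mask(spec.grid)] = i
    return label_map, list(spec.regions)


def simulate_dataset(
    spec: PhantomSpec,
    reversed_pe: bool = False,
) -> tuple[CestStack, CestStack, GroundTruth]:
    """Simulate (distorted EPI stack, undistorted RARE-geometry stack,
    ground truth) for a phantom recipe.

    Per frame the noiseless undistorted image is built from the Lorentzian
    spectra with the per-voxel true ΔB₀ applied as a *spectral* shift, the
    EPI frames are then forward-distorted by the true shift map, the RARE
    twin stays in place, and finally Rician noise is added independently
    per frame.  M0 frames use Z = 1.  ``reversed_pe`` negates the PE
    polarity, so calling once with each value of the flag yields a
    blip-up/blip-down pair with identical noise draws per flag value.
    """
    rng = np.random.default_rng(spec.seed)
    readout = spec.readout.reversed_pe() if reversed_pe else spec.readout
    field = make_field(spec.field_model, spec.grid, seed=spec.seed, f0_mhz=readout.f0_mhz)
    shift = compute_shift_map(field, readout)

    label_map, regions = _region_assignment(spec)
    offsets = np.asarray(spec.schedule.offsets_ppm)
    nx, ny = spec.grid
    n_frames = spec.schedule.n_frames
    clean = np.zeros((nx, ny, n_frames))
    pd_map = np.zeros((nx, ny))

    off_idx = spec.schedule.offset_frame_indices
    m0_idx = spec.schedule.m0_frame_indices
    region_contrast: dict[str, dict[str, float]] = {}
    for i, reg in enumerate(regions):
        vox = label_map == i
        if not vox.any():
            continue
        pd_map[vox] = reg.pd
        zs = synth_zspectrum(reg.pools, offsets, field.delta_b0_ppm[vox])
        frames = np.zeros((int(vox.sum()), n_frames))
        frames[:, off_idx] = zs
        frames[:, m0_idx] = 1.0
        clean[vox, :] = reg.pd * frames
        z0 = synth_zspectrum(reg.pools, offsets, 0.0)
        region_contrast[reg.label] = {
            "mtr_asym_2ppm": _grid_value(offsets, z0, -2.0) - _grid_value(offsets, z0, 2.0),
            "z_at_3p5": _grid_value(offsets, z0, 3.5),
        }

    sigma = 0.0
    if spec.noise.enabled:
        obj = pd_map > 0
        sigma = float(pd_map[obj].mean()) / spec.noise.snr if obj.any() else 0.0

    epi = np.empty_like(clean)
    rare = np.empty_like(clean)
    for f in range(n_frames):
        epi[..., f] = forward_distort(clean[..., f], shift)
        rare[..., f] = clean[..., f]
    if sigma > 0:
        epi = _rician(epi, sigma, rng)
        rare = _rician(rare, sigma, rng)

    epi_stack = CestStack(data=epi, schedule=spec.schedule, readout=readout)
    rare_readout = default_rare_readout(f0_mhz=readout.f0_mhz, n_pe=readout.n_pe, n_fe=readout.n_fe)
    rare_stack = CestStack(data=rare, schedule=spec.schedule, readout=rare_readout)
    gt = GroundTruth(
        clean_stack=CestStack(data=clean, schedule=spec.schedule, readout=readout),
        field=field,
        shift=shift,
        label_map=label_map,
        region_labels=tuple(r.label for r in regions),
        region_contrast=region_contrast,
    )
    return epi_stack, rare_stack, gt


def _grid_value(offsets: np.ndarray, z: np.ndarray, at: float) -> float:
    return float(np.interp(at, offsets, z))


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + g1) + i·g2 with iid Gaussian quadratures."""
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def simulate_two_te_phase(
    field: FieldMap,
    te1_s: float,
    te2_s: float,
    phi0: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """GRE phase images at two echo times: φₖ = wrap(2π·Δf·TEₖ + φ₀)."""
    from .b0map import wrap_phase

    if not 0 < te1_s < te2_s:
        raise ValueError("need te2 > te1 > 0")
    df = field.delta_f_hz
    return (
        wrap_phase(2.0 * np.pi * df * te1_s + phi0),
        wrap_phase(2.0 * np.pi * df * te2_s + phi0),
    )
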