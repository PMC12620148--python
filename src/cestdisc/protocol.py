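"""Saturation-offset schedules and acquisition timing.

A CEST dataset is a sweep of saturation frequency offsets (in ppm relative
to the water resonance) plus a few unsaturated reference frames ("M0"
frames, acquired with the saturation pulse parked far off-resonance,
conventionally at 300 ppm).  This module builds such schedules from
piecewise-uniform segments, keeps the M0 bookkeeping, and computes the
per-image and total scan times for single-shot EPI and RARE readouts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: de-duplication tolerance for offsets (ppm); grid construction in floating
#: point must not create spurious near-duplicates
DEDUP_TOL_PPM = 1e-6

#: conventional far-off-resonance offset for M0 frames (ppm)
M0_OFFSET_PPM = 300.0


@dataclass(frozen=True)
class SaturationSchedule:
    """Ordered saturation offsets plus M0-frame bookkeeping.

    Offsets are stored sorted ascending; acquisition order is metadata
    (``frame_is_m0``), not semantics.  By convention M0 frames come first.
    """

    offsets_ppm: tuple[float, ...]
    m0_offset_ppm: float = M0_OFFSET_PPM
    n_m0: int = 3
    frame_is_m0: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets_ppm, dtype=float)
        if offs.size and not np.all(np.isfinite(offs)):
            raise ValueError("saturation offsets must be finite")
        if offs.size > 1 and np.min(np.diff(np.sort(offs))) <= DEDUP_TOL_PPM:
            raise ValueError("duplicate saturation offsets")
        if self.n_m0 < 1:
            raise ValueError("need at least one M0 frame")
        object.__setattr__(self, "offsets_ppm", tuple(float(x) for x in np.sort(offs)))
        if self.frame_is_m0 is None:
            flags = (True,) * self.n_m0 + (False,) * len(self.offsets_ppm)
            object.__setattr__(self, "frame_is_m0", flags)
        if len(self.frame_is_m0) != self.n_frames or sum(self.frame_is_m0) != self.n_m0:
            raise ValueError("frame_is_m0 inconsistent with offsets/n_m0")

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_ppm)

    @property
    def n_frames(self) -> int:
        """Total frame count = saturation offsets + M0 frames."""
        return self.n_offsets + self.n_m0

    @property
    def offset_frame_indices(self) -> np.ndarray:
        """Frame indices of the non-M0 frames, in acquisition order."""
        return np.flatnonzero(~np.asarray(self.frame_is_m0))

    @property
    def m0_frame_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.frame_is_m0))

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "offsets_ppm": list(self.offsets_ppm),
                "m0_offset_ppm": self.m0_offset_ppm,
                "n_m0": self.n_m0,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SaturationSchedule":
        d = json.loads(text)
        return cls(
            offsets_ppm=tuple(d["offsets_ppm"]),
            m0_offset_ppm=float(d.get("m0_offset_ppm", M0_OFFSET_PPM)),
            n_m0=int(d.get("n_m0", 3)),
        )

    def to_text(self) -> str:
        """One-offset-per-line dialect; M0 frames written at their nominal offset."""
        lines = [repr(self.m0_offset_ppm)] * self.n_m0
        lines += [repr(o) for o in self.offsets_ppm]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, m0_offset_ppm: float = M0_OFFSET_PPM) -> "SaturationSchedule":
        vals = [float(s) for s in text.split()]
        m0 = [v for v in vals if v == m0_offset_ppm]
        offs = [v for v in vals if v != m0_offset_ppm]
        return cls(offsets_ppm=tuple(offs), m0_offset_ppm=m0_offset_ppm, n_m0=len(m0) or 1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            path.write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "SaturationSchedule":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_json(text)
        return cls.from_text(text)


@dataclass(frozen=True)
class ReadoutParams:
    """Readout-module parameters for one image of the CEST sweep.

    ``esp_s`` is the effective echo spacing between successive phase-encode
    lines of the EPI train; it sets the distortion sensitivity and must be
    supplied explicitly (it is rarely printed in methods sections).
    """

    modality: str  # "EPI" or "RARE"
    tr_s: float
    te_s: float = 0.043
    n_pe: int = 96
    n_fe: int = 96
    rare_factor: int | None = None
    esp_s: float | None = None
    pe_polarity: int = +1
    fov_mm: float = 35.0
    f0_mhz: float = 127.7

    def __post_init__(self) -> None:
        if self.modality not in ("EPI", "RARE"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_pe <= 0 or self.tr_s <= 0:
            raise ValueError("n_pe and tr_s must be positive")
        if self.pe_polarity not in (+1, -1):
            raise ValueError("pe_polarity must be +1 or -1")
        if self.modality == "EPI" and self.esp_s is not None and self.esp_s <= 0:
            raise ValueError("esp_s must be positive")

    def reversed_pe(self) -> "ReadoutParams":
        return replace(self, pe_polarity=-self.pe_polarity)


def build_schedule(
    segments: Sequence[tuple[float, float, float]],
    extra_offsets: Iterable[float] = (),
    n_m0: int = 3,
    m0_offset_ppm: float = M0_OFFSET_PPM,
) -> SaturationSchedule:
    """Build a schedule from uniform segments plus individual extra offsets.

    Each segment is ``(start_ppm, stop_ppm, step_ppm)`` with both endpoints
    included.  Offsets that coincide (within ``DEDUP_TOL_PPM``) across
    segments or with extras are de-duplicated, with a logged warning for
    colliding extras.
    """
    offs: list[float] = []
    for start, stop, step in segments:
        if step <= 0:
            raise ValueError(f"segment step must be positive, got {step}")
        lo, hi = min(start, stop), max(start, stop)
        n = int(round((hi - lo) / step))
        if not math.isclose(lo + n * step, hi, abs_tol=DEDUP_TOL_PPM):
            n = int(math.floor((hi - lo) / step + DEDUP_TOL_PPM))
        offs.extend(lo + k * step for k in range(n + 1))
    merged = _dedup(offs)
    for x in extra_offsets:
        if any(abs(x - m) <= DEDUP_TOL_PPM for m in merged):
            logger.warning("extra offset %+.4g ppm collides with a grid point; de-duplicated", x)
        else:
            merged.append(float(x))
    return SaturationSchedule(
        offsets_ppm=tuple(sorted(merged)), m0_offset_ppm=m0_offset_ppm, n_m0=n_m0
    )


def _dedup(values: Iterable[float]) -> list[float]:
    out: list[float] = []
    for v in sorted(values):
        if not out or v - out[-1] > DEDUP_TOL_PPM:
            out.append(float(v))
    return out


def per_image_time(readout: ReadoutParams) -> float:
    """Scan time for one image of the sweep, in seconds.

    Single-shot EPI acquires the whole plane in one TR; RARE needs
    ``ceil(n_pe / rare_factor)`` excitations.
    """
    if readout.modality == "EPI":
        return readout.tr_s
    if readout.rare_factor is None:
        raise ValueError("RARE readout requires rare_factor")
    shots = math.ceil(readout.n_pe / readout.rare_factor)
    return shots * readout.tr_s


def total_scan_time(schedule: SaturationSchedule, readout: ReadoutParams) -> float:
    """Total sweep duration in minutes, rounded to 2 decimals."""
    return round(schedule.n_frames * per_image_time(readout) / 60.0, 2)


# -- the in-protocol recipes ---------------------------------------------


def phantom_3t_schedule(n_m0: int = 3) -> SaturationSchedule:
    """Creatine-phantom sweep: ±10 ppm outer at 1 ppm, ±4 ppm inner at
    0.1 ppm, plus extras around 2 ppm; 106 frames total with 3 M0."""
    return build_schedule(
        segments=[(-4.0, 4.0, 0.1), (-10.0, -4.0, 1.0), (4.0, 10.0, 1.0)],
        extra_offsets=[s * x for s in (+1, -1) for x in (1.75, 1.85, 1.95, 2.05, 2.15)],
        n_m0=n_m0,
    )


def mouse_schedule(n_m0: int = 3) -> SaturationSchedule:
    """In vivo sweep: ±8 ppm at 0.25 ppm, to ±10 at 1 ppm, to ±20 at 5 ppm;
    76 frames total with 3 M0."""
    return build_schedule(
        segments=[
            (-8.0, 8.0, 0.25),
            (-10.0, -8.0, 1.0),
            (8.0, 10.0, 1.0),
            (-20.0, -10.0, 5.0),
            (10.0, 20.0, 5.0),
        ],
        n_m0=n_m0,
    )
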