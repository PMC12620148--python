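"""NIfTI readers/writers and sidecar handling.

Images travel as NIfTI with axis order (x = FE, y = PE, frame); the
saturation schedule rides in a JSON sidecar (``offsets_ppm``,
``m0_offset_ppm``, ``n_m0``).  All images are written float32; field maps
are in ppm and shift maps in pixels, with units recorded in the JSON
metadata written next to each map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .b0map import FieldMap
from .disc import CestStack, ShiftMap
from .protocol import ReadoutParams, SaturationSchedule


def read_cest_nifti(
    path: str | Path,
    sidecar_path: str | Path,
    readout: ReadoutParams | None = None,
) -> CestStack:
    """Load a 4D (or 3D single-frame) CEST stack plus its schedule sidecar."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4:  # (x, y, 1, frame) -> (x, y, frame)
        data = data.reshape(data.shape[0], data.shape[1], -1)
    elif data.ndim == 2:
        data = data[..., None]
    elif data.ndim != 3:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    schedule = SaturationSchedule.load(sidecar_path)
    if data.shape[2] != schedule.n_frames:
        raise ValueError(
            f"NIfTI has {data.shape[2]} frames but the sidecar describes "
            f"{schedule.n_frames}"
        )
    return CestStack(data=data, schedule=schedule, readout=readout, affine=img.affine)


def write_cest_nifti(stack: CestStack, path: str | Path, sidecar_path: str | Path | None = None) -> None:
    affine = stack.affine if stack.affine is not None else np.eye(4)
    nx, ny, nf = stack.data.shape
    img = nib.Nifti1Image(stack.data.reshape(nx, ny, 1, nf).astype(np.float32), affine)
    nib.save(img, str(path))
    if sidecar_path is not None:
        stack.schedule.save(sidecar_path)


def read_mask_nifti(path: str | Path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return np.squeeze(data) > 0


def read_label_nifti(path: str | Path) -> np.ndarray:
    return np.rint(np.squeeze(np.asanyarray(nib.load(str(path)).dataobj))).astype(int)


def write_map_nifti(
    values: np.ndarray,
    path: str | Path,
    units: str,
    meta: dict | None = None,
    affine: np.ndarray | None = None,
) -> None:
    """Write a 2D map as float32 NIfTI plus a JSON metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    info = {"units": units}
    info.update(meta or {})
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    Path(str(sidecar) + ".json").write_text(json.dumps(info, indent=1, default=str))


def write_field_map(fm: FieldMap, path: str | Path) -> None:
    write_map_nifti(
        fm.delta_b0_ppm, path, units="ppm",
        meta={"f0_mhz": fm.f0_mhz, "n_invalid": int((~fm.valid_mask).sum()), **fm.meta},
    )


def read_field_map(path: str | Path) -> FieldMap:
    path = Path(path)
    vals = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj)).astype(float)
    stem = str(path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix(""))
    meta = json.loads(Path(stem + ".json").read_text())
    return FieldMap(
        delta_b0_ppm=vals,
        valid_mask=np.isfinite(vals),
        f0_mhz=float(meta.get("f0_mhz", 127.7)),
        meta=meta,
    )


def write_shift_map(sm: ShiftMap, path: str | Path) -> None:
    write_map_nifti(sm.shift_px, path, units="pixels", meta=sm.provenance)
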