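"""Volume and sidecar I/O.

Volumes travel as NIfTI (via nibabel) with array axes (slice, row, col) and
the anisotropic voxel spacing carried in the header zooms. Wave fields are
written as one NIfTI per (component, frequency) pair with the offset
dimension as the 4th axis, plus a plain-text key=value sidecar describing
frequencies, offsets and voxel size.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import WaveField

__all__ = [
    "read_volume",
    "write_volume",
    "write_wavefield",
    "read_wavefield",
    "read_sidecar",
]

_COMPONENTS = ("x", "y", "z")


def write_volume(
    data: np.ndarray, voxel_size_mm: tuple[float, float, float], path: str | os.PathLike
) -> None:
    """Write a 3D/4D array as NIfTI; spacing ordered (row, col, slice) mm."""
    if len(voxel_size_mm) != 3 or any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel spacing must be 3 positive values (mm)")
    arr = np.asarray(data)
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D volume, got {arr.ndim}D")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([voxel_size_mm[0], voxel_size_mm[1], voxel_size_mm[2], 1.0])
    # store as (row, col, slice[, t]) so the affine spacing is conventional
    moved = np.moveaxis(arr, 0, 2)
    img = nib.Nifti1Image(moved, affine)
    zooms = (float(voxel_size_mm[0]), float(voxel_size_mm[1]), float(voxel_size_mm[2]))
    img.header.set_zooms(zooms + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path: str | os.PathLike):
    """Read a NIfTI volume back to ((slice, row, col[, t]) array, spacing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D volume, got {arr.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("non-positive voxel spacing in header")
    data = np.moveaxis(arr, 2, 0)
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def write_wavefield(wf: WaveField, out_dir: str | os.PathLike, prefix: str = "wave") -> None:
    """One NIfTI per (component, frequency) plus a key=value sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c_idx, comp in enumerate(_COMPONENTS):
        for f_idx, f in enumerate(wf.frequencies_hz):
            vol = wf.displacement[c_idx, f_idx]  # (slice,row,col,offset)
            write_volume(vol, wf.voxel_size_mm, out / f"{prefix}_{comp}_{f:g}Hz.nii")
    lines = [
        f"frequencies_hz={','.join(f'{f:g}' for f in wf.frequencies_hz)}",
        f"n_offsets={wf.n_offsets}",
        f"voxel_size_mm={','.join(f'{v:g}' for v in wf.voxel_size_mm)}",
        f"components={','.join(_COMPONENTS)}",
    ]
    (out / f"{prefix}_meta.txt").write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | os.PathLike) -> dict:
    meta = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_wavefield(in_dir: str | os.PathLike, prefix: str = "wave") -> WaveField:
    """Reassemble a WaveField written by :func:`write_wavefield`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / f"{prefix}_meta.txt"
    if not meta_path.exists():
        raise FileNotFoundError(f"wave-field sidecar not found: {meta_path}")
    meta = read_sidecar(meta_path)
    freqs = tuple(float(x) for x in meta["frequencies_hz"].split(","))
    n_offsets = int(meta["n_offsets"])
    voxel = tuple(float(x) for x in meta["voxel_size_mm"].split(","))
    vols = []
    for comp in _COMPONENTS:
        per_comp = []
        for f in freqs:
            p = in_dir / f"{prefix}_{comp}_{f:g}Hz.nii"
            data, _ = read_volume(p)
            per_comp.append(data)
        vols.append(per_comp)
    disp = np.asarray(vols, dtype=np.float32)
    return WaveField(
        displacement=disp,
        frequencies_hz=freqs,
        voxel_size_mm=voxel,  # type: ignore[arg-type]
        n_offsets=n_offsets,
    )
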