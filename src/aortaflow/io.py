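"""File formats: NIfTI volumes, PLY meshes, CSV tables, JSON metadata.

One acquisition is a directory holding three 4D velocity-component files
(``vel_x.nii``, ``vel_y.nii``, ``vel_z.nii``, m/s, world-axis components),
one 4D magnitude file (``mag.nii``), and a JSON sidecar declaring venc,
frame duration, and voxel size.  Ground-truth files from the phantom
generator (``truth_mask.nii``, ``truth.json``) ride along when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .datatypes import LumenMask, SurfaceMesh, VelocityField4D

__all__ = ["save_dataset", "load_dataset", "save_mask", "load_mask",
           "save_mesh_ply", "write_json", "read_json"]

_COMPONENTS = ("vel_x.nii", "vel_y.nii", "vel_z.nii")


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def _to_nifti_4d(arr: np.ndarray, voxel_size) -> nib.Nifti1Image:
    # internal order (T, x, y, z) -> NIfTI (x, y, z, T)
    data = np.moveaxis(arr, 0, -1).astype(np.float32)
    return nib.Nifti1Image(data, _affine(voxel_size))


def save_dataset(out_dir, field: VelocityField4D, magnitude: np.ndarray,
                 truth_mask: np.ndarray | None = None,
                 truth_params: dict | None = None) -> Path:
    """Write velocity components, magnitude, sidecar, and optional truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(_COMPONENTS):
        nib.save(_to_nifti_4d(field.values[..., c], field.voxel_size),
                 out / name)
    nib.save(_to_nifti_4d(np.asarray(magnitude), field.voxel_size),
             out / "mag.nii")
    sidecar = {
        "venc_m_per_s": list(map(float, field.venc)),
        "frame_duration_ms": float(field.frame_duration),
        "voxel_size_mm": list(map(float, field.voxel_size)),
        "n_frames": int(field.n_frames),
        "component_axes": ["x", "y", "z"],
        "component_sign": [1, 1, 1],
    }
    write_json(out / "sidecar.json", sidecar)
    if truth_mask is not None:
        nib.save(nib.Nifti1Image(truth_mask.astype(np.uint8),
                                 _affine(field.voxel_size)),
                 out / "truth_mask.nii")
    if truth_params is not None:
        write_json(out / "truth.json", truth_params)
    return out


def load_dataset(in_dir) -> tuple[VelocityField4D, np.ndarray]:
    """Load one acquisition directory; raises naming any missing file."""
    in_dir = Path(in_dir)
    for name in _COMPONENTS + ("mag.nii", "sidecar.json"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"missing input file: {in_dir / name}")
    sidecar = read_json(in_dir / "sidecar.json")
    comps = []
    for name in _COMPONENTS:
        img = nib.load(in_dir / name)
        comps.append(np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0))
    vals = np.stack(comps, axis=-1)
    mag_img = nib.load(in_dir / "mag.nii")
    magnitude = np.moveaxis(np.asarray(mag_img.dataobj, dtype=float), -1, 0)
    field = VelocityField4D(vals, sidecar["voxel_size_mm"],
                            sidecar["frame_duration_ms"],
                            sidecar["venc_m_per_s"])
    return field, magnitude


def save_mask(path, mask: LumenMask) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8),
                             _affine(mask.voxel_size)), str(path))


def load_mask(path, voxel_size) -> LumenMask:
    img = nib.load(str(path))
    return LumenMask(np.asarray(img.dataobj) > 0, voxel_size,
                     provenance={"source": str(path)})


def save_mesh_ply(path, mesh: SurfaceMesh,
                  vertex_scalars: dict | None = None) -> None:
    """Export the surface as ascii PLY with optional per-vertex scalars."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    if vertex_scalars:
        for name, vals in vertex_scalars.items():
            tm.vertex_attributes[name] = np.asarray(vals, dtype=np.float32)
    tm.export(str(path), encoding="ascii")


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
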