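"""Readers and writers: HDF5 / TIFF-stack label volumes, STL meshes, tables.

HDF5 volumes are self-contained: one ``labels`` dataset plus a JSON-string
attribute carrying pitch, axes and origin.  TIFF stacks (one page per
rostro-caudal section) carry no standard 3D pitch, so a JSON sidecar
(``<path>.meta.json``) is written alongside; reading a TIFF without sidecar
or an explicit pitch raises, never silently assumes isotropy.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import trimesh
from skimage import measure

from .model import AnnotatedVolume, TonotopicFrame, VolumeMetadataError

_H5_META_ATTR = "calyxmorph_meta"


def _meta_dict(volume: AnnotatedVolume) -> dict:
    return {
        "voxel_pitch_nm": list(volume.voxel_pitch_nm),
        "axes": list(volume.axes),
        "origin_offset_nm": list(volume.origin_offset_nm),
    }


def write_volume(volume: AnnotatedVolume, path: str | Path) -> Path:
    """Write a labeled volume to ``.h5``/``.hdf5`` or ``.tif``/``.tiff``."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels", data=volume.labels, compression="gzip")
            ds.attrs[_H5_META_ATTR] = json.dumps(_meta_dict(volume))
    elif suffix in (".tif", ".tiff"):
        # pages along Z: page k is the (X, Y) section at rostro-caudal index k
        tifffile.imwrite(path, np.moveaxis(volume.labels, 2, 0),
                         photometric="minisblack")
        sidecar = path.with_name(path.name + ".meta.json")
        sidecar.write_text(json.dumps(_meta_dict(volume), indent=1))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path: str | Path, voxel_pitch_nm=None) -> AnnotatedVolume:
    """Read a labeled volume; pitch must come from metadata or the caller."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["labels"]
            labels = ds[()]
            raw = ds.attrs.get(_H5_META_ATTR)
            if raw is None and voxel_pitch_nm is None:
                raise VolumeMetadataError(
                    f"{path}: no pitch metadata stored and none supplied"
                )
            meta = json.loads(raw) if raw is not None else {}
    elif suffix in (".tif", ".tiff"):
        labels = np.moveaxis(tifffile.imread(path), 0, 2)
        sidecar = path.with_name(path.name + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        elif voxel_pitch_nm is not None:
            meta = {}
        else:
            raise VolumeMetadataError(
                f"{path}: TIFF stacks carry no voxel pitch; provide voxel_pitch_nm "
                f"or a {sidecar.name} sidecar"
            )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")

    pitch = voxel_pitch_nm if voxel_pitch_nm is not None else meta.get("voxel_pitch_nm")
    if pitch is None:
        raise VolumeMetadataError(f"{path}: missing voxel pitch metadata")
    kwargs = {}
    if "axes" in meta:
        kwargs["axes"] = tuple(meta["axes"])
    if "origin_offset_nm" in meta:
        kwargs["origin_offset_nm"] = tuple(meta["origin_offset_nm"])
    return AnnotatedVolume(labels=labels, voxel_pitch_nm=tuple(pitch), **kwargs)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def segment_mesh(volume: AnnotatedVolume, segment_id: int) -> trimesh.Trimesh:
    """Triangle surface mesh of one segment, in micrometre coordinates.

    Marching cubes runs on the zero-padded binary mask with the anisotropic
    physical spacing, so mesh volume converges to the voxel volume for
    smooth blobs (within 5% for diameters >= 5 um at reasonable sampling).
    """
    sub, origin = volume.crop_for(segment_id, margin=1)
    mask = np.pad((sub == segment_id).astype(np.uint8), 1)
    spacing = tuple(volume.pitch_um)
    verts, faces, _, _ = measure.marching_cubes(mask, level=0.5, spacing=spacing)
    # undo the one-voxel pad and shift to parent-grid physical coordinates;
    # voxel centers sit at (i + 0.5) * pitch
    verts = verts + (origin - 1 + 0.5) * volume.pitch_um
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def export_mesh(volume: AnnotatedVolume, segment_id: int, path: str | Path) -> Path:
    """Write one segment's surface as an STL file (micrometre units)."""
    if not (volume.labels == segment_id).any():
        raise ValueError(f"segment {segment_id} is empty")
    mesh = segment_mesh(volume, segment_id)
    path = Path(path)
    mesh.export(path)
    return path


# ---------------------------------------------------------------------------
# tables and frames
# ---------------------------------------------------------------------------

def write_segment_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_segment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_frame(frame: TonotopicFrame, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(frame.to_dict(), indent=1))
    return path


def read_frame(path: str | Path) -> TonotopicFrame:
    return TonotopicFrame.from_dict(json.loads(Path(path).read_text()))
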