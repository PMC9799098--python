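"""Core data model: labeled anisotropic volumes, segment tables, tonotopic frames.

The substrate of every measurement in this package is a 3D integer label grid
on an anisotropic voxel lattice (serial block-face EM convention: fine in-plane
pixels, coarser section thickness).  Axis order is (X, Y, Z) =
(dorso-ventral, medio-lateral, rostro-caudal); the medio-lateral Y axis is the
tonotopic axis of the MNTB (lateral = low frequency, medial = high frequency).

Coordinate convention: 0-based voxel indices; voxel ``(i, j, k)`` spans the
half-open physical box ``[i*px, (i+1)*px) x ... `` and its center sits at
``(i + 0.5) * pitch``.  Centroids and all physical measurements use voxel
centers, so physical extent is exactly ``shape * pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

DEFAULT_AXES = ("dorso-ventral", "medio-lateral", "rostro-caudal")

#: medio-lateral (tonotopic) axis index in the (X, Y, Z) convention
TONOTOPIC_AXIS = 1


class SegmentClass(str, Enum):
    """Biological class of a segment in the label volume."""

    PN_SOMA = "PN_SOMA"          # principal neuron cell body
    CALYX = "CALYX"              # calyx of Held terminal (incl. its axon cone)
    NONCALYCEAL = "NONCALYCEAL"  # small bouton-type synaptic input
    PIGMENT = "PIGMENT"          # intracellular age pigment (lipofuscin-like)
    OTHER = "OTHER"


class VolumeMetadataError(ValueError):
    """Raised when voxel pitch / axis metadata is missing or inconsistent."""


class MissingClassError(KeyError):
    """Raised when label ids in a volume have no class assignment."""

    def __init__(self, missing_ids: Sequence[int]):
        self.missing_ids = sorted(int(i) for i in missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} segment id(s) missing from class map: "
            f"{self.missing_ids[:20]}{'...' if len(self.missing_ids) > 20 else ''}"
        )


@dataclass
class AnnotatedVolume:
    """A labeled segmentation volume with physical voxel pitch.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, positive values are segment ids.
    voxel_pitch_nm
        Physical voxel size per axis in nanometres, e.g. ``(15, 15, 50)`` for
        the native SBEM convention or a coarsened desk-scale pitch.
    axes
        Ordered anatomical axis names.
    origin_offset_nm
        Physical position of voxel (0, 0, 0); purely informational.
    """

    labels: np.ndarray
    voxel_pitch_nm: tuple[float, float, float]
    axes: tuple[str, str, str] = DEFAULT_AXES
    origin_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.voxel_pitch_nm = tuple(float(p) for p in self.voxel_pitch_nm)
        if len(self.voxel_pitch_nm) != 3 or any(p <= 0 for p in self.voxel_pitch_nm):
            raise VolumeMetadataError(
                f"voxel pitch must be 3 strictly positive values, got {self.voxel_pitch_nm}"
            )
        if len(self.axes) != 3:
            raise VolumeMetadataError("axes must name exactly 3 axes")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def pitch_um(self) -> np.ndarray:
        return np.asarray(self.voxel_pitch_nm, dtype=float) / 1000.0

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.pitch_um))

    @property
    def extent_um(self) -> np.ndarray:
        """Physical extent per axis in micrometres (= shape * pitch, exact)."""
        return np.asarray(self.shape, dtype=float) * self.pitch_um

    # -- segments -----------------------------------------------------------
    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def segment_mask(self, segment_id: int) -> np.ndarray:
        return self.labels == segment_id

    def crop_for(self, segment_ids: int | Iterable[int], margin: int = 0):
        """Bounding-box crop covering the given segment(s) plus a voxel margin.

        Returns ``(sub_labels, origin_index)`` where ``origin_index`` is the
        voxel index of the crop's (0,0,0) corner in the parent grid.
        """
        if np.isscalar(segment_ids):
            segment_ids = [int(segment_ids)]
        mask = np.isin(self.labels, list(segment_ids))
        if not mask.any():
            raise ValueError(f"segments {list(segment_ids)} are empty")
        idx = np.nonzero(mask)
        lo = [max(0, int(i.min()) - margin) for i in idx]
        hi = [min(s, int(i.max()) + 1 + margin) for i, s in zip(idx, self.shape)]
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        return self.labels[sl], np.asarray(lo)


@dataclass
class TonotopicFrame:
    """Partition of the medio-lateral (tonotopic) axis into three regions.

    The lateral third maps to low sound frequencies (LF) and the medial third
    to high frequencies (HF); the middle third is the central region.  The cut
    positions default to equal thirds of the axis but are configurable.
    """

    lateral_end_um: float
    medial_end_um: float
    region_bounds_um: tuple[float, float] = None  # type: ignore[assignment]
    axis: int = TONOTOPIC_AXIS

    def __post_init__(self) -> None:
        if self.medial_end_um <= self.lateral_end_um:
            raise ValueError("medial_end_um must exceed lateral_end_um")
        if self.region_bounds_um is None:
            span = self.medial_end_um - self.lateral_end_um
            self.region_bounds_um = (
                self.lateral_end_um + span / 3.0,
                self.lateral_end_um + 2.0 * span / 3.0,
            )
        b1, b2 = self.region_bounds_um
        if not (self.lateral_end_um < b1 < b2 < self.medial_end_um):
            raise ValueError(
                "region bounds must be ordered and strictly inside the axis range"
            )

    @classmethod
    def from_volume(cls, volume: AnnotatedVolume, axis: int = TONOTOPIC_AXIS) -> "TonotopicFrame":
        return cls(0.0, float(volume.extent_um[axis]), axis=axis)

    # regions tile the axis: lateral [lat, b1), central [b1, b2), medial [b2, med]
    def region_of(self, coord_um: float) -> str:
        b1, b2 = self.region_bounds_um
        if not (self.lateral_end_um <= coord_um <= self.medial_end_um):
            raise ValueError(f"coordinate {coord_um} outside tonotopic axis range")
        if coord_um < b1:
            return "lateral"
        if coord_um < b2:
            return "central"
        return "medial"

    def frequency_of(self, region: str) -> str | None:
        return {"lateral": "LF", "medial": "HF", "central": None}[region]

    def region_interval_um(self, region: str) -> tuple[float, float]:
        b1, b2 = self.region_bounds_um
        return {
            "lateral": (self.lateral_end_um, b1),
            "central": (b1, b2),
            "medial": (b2, self.medial_end_um),
        }[region]

    def to_dict(self) -> dict:
        return {
            "lateral_end_um": self.lateral_end_um,
            "medial_end_um": self.medial_end_um,
            "region_bounds_um": list(self.region_bounds_um),
            "axis": self.axis,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TonotopicFrame":
        return cls(
            lateral_end_um=float(d["lateral_end_um"]),
            medial_end_um=float(d["medial_end_um"]),
            region_bounds_um=tuple(d["region_bounds_um"]),
            axis=int(d.get("axis", TONOTOPIC_AXIS)),
        )


# ---------------------------------------------------------------------------
# segment table
# ---------------------------------------------------------------------------

#: PN soma acceptance screen (equivalent-sphere diameter, micrometres)
PN_DIAMETER_SCREEN_UM = (20.0, 30.0)

SEGMENT_TABLE_COLUMNS = [
    "segment_id",
    "klass",
    "voxel_count",
    "volume_um3",
    "surface_area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "equivalent_diameter_um",
    "accepted",
]


def equivalent_diameter_um(volume_um3: float | np.ndarray) -> float | np.ndarray:
    """Equivalent-sphere diameter from volume: d = (6 V / pi)^(1/3)."""
    return (6.0 * np.asarray(volume_um3) / np.pi) ** (1.0 / 3.0)


def _exposed_face_area_um2(mask: np.ndarray, pitch_um: np.ndarray) -> float:
    """Surface area by counting exposed voxel faces, weighted by face area.

    A face is exposed where a segment voxel borders a non-segment voxel
    (or the array boundary).  Face areas are the products of the two pitches
    orthogonal to the face normal, so the estimate respects anisotropy.  Note
    this voxel-face area overestimates a smooth surface (by ~1.5x for a
    sphere); it is deterministic and is never mixed with mesh-based areas.
    """
    px, py, pz = pitch_um
    face_area = (py * pz, px * pz, px * py)
    total = 0.0
    for axis, fa in enumerate(face_area):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        diff = mask[tuple(sl_a)] != mask[tuple(sl_b)]
        n = int(diff.sum())
        # faces against the array boundary
        sl_lo = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = -1
        n += int(mask[tuple(sl_lo)].sum()) + int(mask[tuple(sl_hi)].sum())
        total += n * fa
    return total


def derive_segment_table(
    volume: AnnotatedVolume,
    class_map: Mapping[int, SegmentClass | str],
    size_screen_um: tuple[float, float] = PN_DIAMETER_SCREEN_UM,
    screen_tolerance_um: float = 0.0,
) -> pd.DataFrame:
    """Per-segment geometry table in physical units.

    Every nonzero label must appear in ``class_map`` (a
    :class:`MissingClassError` lists offenders otherwise).  Volume is exactly
    ``voxel count x voxel volume``; surface area is exposed-face area on the
    anisotropic grid; centroids are means of voxel centers.  PN somas are
    flagged ``accepted`` when their equivalent-sphere diameter passes the
    20-30 um screen (widened by ``screen_tolerance_um`` on both sides);
    non-PN segments are always accepted.
    """
    ids = volume.segment_ids()
    missing = [int(i) for i in ids if int(i) not in class_map]
    if missing:
        raise MissingClassError(missing)

    pitch = volume.pitch_um
    vox_vol = volume.voxel_volume_um3
    rows = []
    objects = ndi.find_objects(volume.labels)
    for seg_id in ids:
        seg_id = int(seg_id)
        sl = objects[seg_id - 1]
        sub = volume.labels[sl] == seg_id
        count = int(sub.sum())
        vol_um3 = count * vox_vol
        area = _exposed_face_area_um2(sub, pitch)
        idx = np.nonzero(sub)
        origin = np.array([s.start for s in sl], dtype=float)
        centroid = (np.array([i.mean() for i in idx]) + origin + 0.5) * pitch
        eq_d = float(equivalent_diameter_um(vol_um3))
        klass = SegmentClass(class_map[seg_id])
        if klass is SegmentClass.PN_SOMA:
            lo, hi = size_screen_um
            accepted = (lo - screen_tolerance_um) <= eq_d <= (hi + screen_tolerance_um)
        else:
            accepted = True
        rows.append(
            dict(
                segment_id=seg_id,
                klass=klass.value,
                voxel_count=count,
                volume_um3=vol_um3,
                surface_area_um2=area,
                centroid_x_um=centroid[0],
                centroid_y_um=centroid[1],
                centroid_z_um=centroid[2],
                equivalent_diameter_um=eq_d,
                accepted=bool(accepted),
            )
        )
    if not rows:
        return pd.DataFrame(columns=SEGMENT_TABLE_COLUMNS)
    return pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)


def segments_of_class(table: pd.DataFrame, klass: SegmentClass | str) -> list[int]:
    klass = SegmentClass(klass).value
    return [int(i) for i in table.loc[table["klass"] == klass, "segment_id"]]
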