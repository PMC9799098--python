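"""Cell-density estimation along the tonotopic axis.

Whole-volume density is a straight count divided by physical volume.
Regional densities follow the cube-sampling protocol: a 70 um cube is placed
at random (uniformly over admissible origins) four times per tonotopic
region, cells are counted with the *60%-in-two-planes* inclusion rule, and
the count is averaged.  A cell is "inside" a cube when at least 60% of its
projected footprint (the voxel-column shadow of the cell on each of the
three axis-aligned planes) lies inside the cube's projected square, in at
least two of the three planes.

Note: this inclusion rule is not an unbiased counting frame.  A convex cell
of radius r is excluded once its center comes within ~0.158 r of a cube
face, so the effective sampling volume is roughly (L - 0.32 r)^3 and
absolute cube densities undercount by ~13-15% for 20-30 um cells in 70 um
cubes.  The regional *percentages* (LF vs HF shares) divide out this
multiplicative bias, which is why they, and not the absolute cube counts,
are the quantity reported along the tonotopic axis.  See the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .model import AnnotatedVolume, TonotopicFrame

CUBE_SIDE_UM = 70.0
INCLUSION_FRACTION = 0.60
_PLANES = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class SamplingCube:
    """An axis-aligned sampling cube; origin is the lower corner in um."""

    origin_um: tuple[float, float, float]
    side_um: float = CUBE_SIDE_UM
    region: str = ""

    @property
    def volume_mm3(self) -> float:
        return (self.side_um**3) * 1e-9


def total_density(n_cells: int, volume_mm3: float) -> float:
    """Whole-volume density in cells/mm^3."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    return n_cells / volume_mm3


def percent_decline(d_from: float, d_to: float) -> int:
    """Percent loss between two densities, rounded half-up to an integer."""
    if d_from <= 0:
        raise ValueError("reference density must be positive")
    loss = 100.0 * (d_from - d_to) / d_from
    return int(np.floor(loss + 0.5))


def regional_percent(d_lf: float, d_hf: float) -> tuple[float, float]:
    """Densities normalized to the LF+HF total, in percent (sums to 100)."""
    s = d_lf + d_hf
    if s <= 0:
        raise ValueError("at least one regional density must be positive")
    return 100.0 * d_lf / s, 100.0 * d_hf / s


def extrapolate_total_pn(
    count: int, imaged_depth_um: float, full_depth_um: float = 800.0
) -> int:
    """Whole-nucleus cell count from a partial rostro-caudal sample.

    Scales the imaged count by the depth ratio and reports two significant
    figures (e.g. 221 cells in 80 of 800 um -> 2,200 per nucleus).
    """
    if imaged_depth_um <= 0 or full_depth_um <= 0:
        raise ValueError("depths must be positive")
    est = count * full_depth_um / imaged_depth_um
    if est == 0:
        return 0
    mag = 10 ** (int(np.floor(np.log10(abs(est)))) - 1)
    return int(np.floor(est / mag + 0.5) * mag)


# ---------------------------------------------------------------------------
# the inclusion rule
# ---------------------------------------------------------------------------

def projected_fraction_inside(
    voxels: np.ndarray, plane: tuple[int, int], cube: SamplingCube,
    pitch_um: np.ndarray,
) -> float:
    """Fraction of the cell's footprint on one plane inside the cube square.

    ``voxels`` is the (n, 3) integer voxel index array of the cell; the
    footprint is the set of distinct voxel columns, tested at voxel centers.
    """
    cols = np.unique(voxels[:, plane], axis=0)
    centers = (cols + 0.5) * pitch_um[list(plane)]
    lo = np.asarray(cube.origin_um)[list(plane)]
    inside = np.all((centers >= lo) & (centers < lo + cube.side_um), axis=1)
    return float(inside.mean())


def cell_in_cube(
    voxels: np.ndarray, cube: SamplingCube, pitch_um,
    threshold: float = INCLUSION_FRACTION,
) -> bool:
    """True when >= 60% of the footprint is inside in >= 2 of the 3 planes."""
    if len(voxels) == 0:
        raise ValueError("cell has no voxels")
    pitch_um = np.asarray(pitch_um, dtype=float)
    hits = sum(
        projected_fraction_inside(voxels, p, cube, pitch_um) >= threshold
        for p in _PLANES
    )
    return hits >= 2


# ---------------------------------------------------------------------------
# cube placement and counting
# ---------------------------------------------------------------------------

def place_cubes(
    frame: TonotopicFrame,
    region: str,
    volume_extent_um,
    n: int = 4,
    side_um: float = CUBE_SIDE_UM,
    rng: np.random.Generator | int | None = None,
) -> list[SamplingCube]:
    """Uniformly sample cube origins inside one region's slab.

    The cube must lie entirely inside the volume and inside the region's
    medio-lateral slab; origins are continuous-uniform over the admissible
    box and may overlap between draws (the protocol does not forbid it).
    Raises when the region cannot contain the cube.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ext = np.asarray(volume_extent_um, dtype=float)
    lo = np.zeros(3)
    hi = ext - side_um
    a, b = frame.region_interval_um(region)
    lo[frame.axis] = a
    hi[frame.axis] = b - side_um
    if np.any(hi < lo):
        bad = [i for i in range(3) if hi[i] < lo[i]]
        raise ValueError(
            f"region {region!r} cannot contain a {side_um} um cube along "
            f"axes {bad}; use a smaller cube side"
        )
    cubes = []
    for _ in range(n):
        origin = lo + rng.random(3) * (hi - lo)
        cubes.append(SamplingCube(tuple(float(x) for x in origin), side_um, region))
    return cubes


class CellFootprints:
    """Cached per-plane footprint column centers, for repeated cube queries.

    Counting with the inclusion rule over many cube placements only needs,
    per cell and plane, the physical centers of the distinct voxel columns;
    these are extracted once.
    """

    def __init__(self, volume: AnnotatedVolume, segment_ids):
        self.pitch_um = volume.pitch_um
        self.centers: dict[int, list[np.ndarray]] = {}
        self.centroids_um: dict[int, np.ndarray] = {}
        self.radii_um: dict[int, float] = {}
        objects = ndi.find_objects(volume.labels)
        for sid in segment_ids:
            sid = int(sid)
            sl = objects[sid - 1]
            if sl is None:
                continue
            sub = volume.labels[sl] == sid
            origin = np.array([s.start for s in sl])
            per_plane = []
            for p in _PLANES:
                drop_axis = ({0, 1, 2} - set(p)).pop()
                cols = np.argwhere(sub.any(axis=drop_axis)) + origin[list(p)]
                per_plane.append((cols + 0.5) * self.pitch_um[list(p)])
            self.centers[sid] = per_plane
            idx = np.nonzero(sub)
            c = (np.array([i.mean() for i in idx]) + origin + 0.5) * self.pitch_um
            self.centroids_um[sid] = c
            span = (np.array([i.max() - i.min() + 1 for i in idx])) * self.pitch_um
            self.radii_um[sid] = float(span.max()) / 2.0

    def cell_in_cube(self, sid: int, cube: SamplingCube,
                     threshold: float = INCLUSION_FRACTION) -> bool:
        hits = 0
        for plane, centers in zip(_PLANES, self.centers[sid]):
            lo = np.asarray(cube.origin_um)[list(plane)]
            inside = np.all((centers >= lo) & (centers < lo + cube.side_um),
                            axis=1)
            hits += float(inside.mean()) >= threshold
        return hits >= 2

    def count_in_cube(self, cube: SamplingCube) -> int:
        n = 0
        lo = np.asarray(cube.origin_um)
        hi = lo + cube.side_um
        for sid in self.centers:
            c = self.centroids_um[sid]
            r = self.radii_um[sid] + 1.0
            if np.any(c < lo - r) or np.any(c > hi + r):
                continue
            if self.cell_in_cube(sid, cube):
                n += 1
        return n


@dataclass
class DensityEstimate:
    region: str
    cube_counts: list[int]
    side_um: float

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.cube_counts))

    @property
    def sem_count(self) -> float:
        c = np.asarray(self.cube_counts, dtype=float)
        return float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else float("nan")

    @property
    def cube_volume_mm3(self) -> float:
        return (self.side_um**3) * 1e-9

    @property
    def density_mm3(self) -> float:
        return self.mean_count / self.cube_volume_mm3


def regional_density(
    volume: AnnotatedVolume,
    pn_ids,
    frame: TonotopicFrame,
    n_cubes: int = 4,
    side_um: float = CUBE_SIDE_UM,
    rng: np.random.Generator | int | None = None,
    footprints: CellFootprints | None = None,
) -> dict[str, DensityEstimate]:
    """Cube-sampled density per tonotopic region (mean of n cube counts)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fp = footprints if footprints is not None else CellFootprints(volume, pn_ids)
    out = {}
    for region in ("lateral", "central", "medial"):
        cubes = place_cubes(frame, region, volume.extent_um, n_cubes, side_um, rng)
        counts = [fp.count_in_cube(c) for c in cubes]
        out[region] = DensityEstimate(region, counts, side_um)
    return out
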