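"""Synthetic SBEM-like labeled volumes with exact ground truth.

The raw serial block-face EM volumes behind the original MNTB study are not
publicly deposited, so every downstream stage here is exercised on generated
label volumes that emulate the relevant geometry at a coarsened, desk-scale
voxel pitch (a few hundred nanometres instead of 15 x 15 x 50 nm; all
algorithms accept any pitch):

* principal-neuron (PN) somas: non-overlapping superellipsoid blobs of
  20-30 um diameter, optionally thinned along the medio-lateral axis to
  produce a tonotopic (LF:HF) density gradient;
* calyx of Held terminals: shell sectors wrapping a controllable fraction of
  the host soma surface, with a thin axon cone and a controllable number of
  outward swelling lobes;
* non-calyceal boutons: small spheres apposed to the soma surface;
* age pigments: intracellular spots with a controllable size distribution;
* degeneration: calyx fragmentation (>= 3 disconnected pieces) and PN
  membrane roughening (correlated radial carving).

Every realized quantity (counts, achieved coverage fractions, spot
diameters, degeneration flags) is recorded in a :class:`GroundTruthManifest`
that serves as the recovery oracle for the measurement modules.  A fixed
seed makes the output bit-exact reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .model import AnnotatedVolume, SegmentClass, TonotopicFrame, derive_segment_table
from ._morph import surface_voxels

# label-id blocks per class; keeps ids readable and collision free
PN_ID_BASE = 1
CALYX_ID_BASE = 1001
BOUTON_ID_BASE = 10001
PIGMENT_ID_BASE = 50001

_SIX_CONN = ndi.generate_binary_structure(3, 1)


class PackingError(RuntimeError):
    """Requested geometry cannot be realized (too dense / too large)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BoutonSpec:
    """Non-calyceal bouton inputs; counts drawn Poisson with a medio-lateral
    gradient from ``lf_mean`` (lateral end) to ``hf_mean`` (medial end),
    mirroring the larger HF bouton counts reported for young MNTB."""

    lf_mean: float = 74.0
    hf_mean: float = 90.0
    radius_um: float = 0.75
    min_contact_faces: int = 5


@dataclass
class PigmentSpec:
    """Age-pigment spots per cell.  Diameters are log-normal in micrometres
    (geometric mean ``diam_gm_um``), clipped to a plausible EM range."""

    count_mean: float = 3.0
    diam_gm_um: float = 1.8
    diam_log_sigma: float = 0.35
    min_diam_um: float = 0.7
    max_diam_um: float = 5.2


@dataclass
class DegenerationSpec:
    """Fractions of structures mutated by :func:`apply_degeneration`."""

    ch_fragment_fraction: float = 0.0
    pn_rough_fraction: float = 0.0
    rough_amplitude: float = 0.18   # max radial carve depth, fraction of radius
    rough_sigma_vox: float = 3.0    # correlation length of the carving noise


@dataclass
class SimulationConfig:
    """Full description of one synthetic MNTB scene.

    The defaults describe a desk-scale slab of nucleus (a 200 x 240 x 200 um
    block at 600 nm pitch, ~33,000 cells/mm^3) populated with somas only,
    sized so each tonotopic region holds ~10 sampling-cube volumes; use the
    presets
    (:meth:`stereology`, :meth:`morphometry`, :meth:`single_pn`,
    :meth:`degeneration_preset`, :meth:`tiny`) for the standard study
    conditions of each analysis stage.
    """

    volume_shape_um: tuple[float, float, float] = (200.0, 240.0, 200.0)
    voxel_pitch_nm: tuple[float, float, float] = (600.0, 600.0, 600.0)
    n_pn: int = 320
    soma_diameter_um: tuple[float, float] = (20.0, 26.0)
    superellipsoid_exponent: float = 2.2
    eccentricity: float = 0.05
    placement: str = "random"             # "random" | "line"
    min_gap_um: float = 0.8               # minimum surface-to-surface gap
    boundary: str = "clip"                # "clip" | "inset"
    density_gradient: tuple[float, float] = (55.0, 45.0)   # LF:HF
    coverage_targets: Optional[object] = None  # None | (lo, hi) | sequence
    poly_fraction: float = 0.0
    secondary_coverage: tuple[float, float] = (0.10, 0.20)
    swelling_counts: Optional[object] = None   # None | (lo, hi) | sequence
    shell_thickness_um: float = 1.5
    lobe_radius_um: float = 3.0
    axon_radius_um: float = 1.0
    boutons: Optional[BoutonSpec] = None
    pigment: Optional[PigmentSpec] = None
    degeneration: Optional[DegenerationSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pn < 0:
            raise ValueError("n_pn must be >= 0")
        if not (0.0 <= self.poly_fraction <= 1.0):
            raise ValueError("poly_fraction must be in [0, 1]")
        if self.placement not in ("random", "line"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.boundary not in ("clip", "inset"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if self.lobe_radius_um < 2.0 * self.shell_thickness_um:
            raise ValueError(
                "lobe_radius_um must be >= 2x shell_thickness_um for the "
                "swelling counter's calibrated recovery regime"
            )
        if self.degeneration is not None:
            d = self.degeneration
            for f in (d.ch_fragment_fraction, d.pn_rough_fraction):
                if not (0.0 <= f <= 1.0):
                    raise ValueError("degeneration fractions must be in [0, 1]")

    # -- presets ------------------------------------------------------------
    @classmethod
    def stereology(cls, seed: int = 0, n_pn: int = 320) -> "SimulationConfig":
        """Homogeneous-with-gradient soma field for density estimation."""
        return cls(n_pn=n_pn, seed=seed)

    @classmethod
    def morphometry(cls, seed: int = 0, n_pn: int = 12) -> "SimulationConfig":
        """12 cells along the tonotopic axis with calyces, boutons, pigments:
        the per-cell reconstruction scenario (innervation, calyx typing)."""
        return cls(
            volume_shape_um=(84.0, 220.0, 60.0),
            voxel_pitch_nm=(300.0, 300.0, 300.0),
            n_pn=n_pn,
            soma_diameter_um=(20.0, 23.0),
            placement="line",
            boundary="inset",
            coverage_targets=(0.25, 0.45),
            poly_fraction=0.25,
            swelling_counts=(0, 17),
            boutons=BoutonSpec(),
            pigment=PigmentSpec(),
            seed=seed,
        )

    @classmethod
    def single_pn(
        cls,
        coverage: float,
        seed: int = 0,
        voxel_pitch_nm: float = 100.0,
        n_swellings: int = 0,
    ) -> "SimulationConfig":
        """One isolated PN + calyx at fine pitch for coverage recovery.

        At 100 nm pitch a ~24 um soma spans ~240 voxels, large enough that
        the rim-spill discretization bias of the dilation-shell coverage
        measurement stays well below 3 percentage points.
        """
        d_hi = 24.5
        shell = 1.0
        lobe_reach = 2.0 * 3.0 if n_swellings > 0 else 0.0
        extent = d_hi * 1.05 + 2.0 * (shell + lobe_reach + 1.2)
        return cls(
            volume_shape_um=(extent, extent, extent),
            voxel_pitch_nm=(voxel_pitch_nm,) * 3,
            n_pn=1,
            soma_diameter_um=(23.5, d_hi),
            placement="line",
            boundary="inset",
            coverage_targets=[coverage],
            swelling_counts=[n_swellings],
            shell_thickness_um=shell,
            seed=seed,
        )

    @classmethod
    def degeneration_preset(cls, seed: int = 0, n_pn: int = 8) -> "SimulationConfig":
        return cls(
            volume_shape_um=(70.0, 180.0, 60.0),
            voxel_pitch_nm=(400.0, 400.0, 400.0),
            n_pn=n_pn,
            soma_diameter_um=(20.0, 24.0),
            placement="line",
            boundary="inset",
            coverage_targets=(0.25, 0.40),
            swelling_counts=(0, 10),
            pigment=PigmentSpec(),
            degeneration=DegenerationSpec(
                ch_fragment_fraction=0.5, pn_rough_fraction=0.4
            ),
            seed=seed,
        )

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimulationConfig":
        """Smallest end-to-end scene, for pipeline smoke runs."""
        return cls(
            volume_shape_um=(50.0, 120.0, 45.0),
            voxel_pitch_nm=(500.0, 500.0, 500.0),
            n_pn=4,
            soma_diameter_um=(20.0, 22.0),
            placement="line",
            boundary="inset",
            coverage_targets=(0.25, 0.40),
            poly_fraction=0.25,
            swelling_counts=(0, 8),
            boutons=BoutonSpec(lf_mean=8.0, hf_mean=12.0),
            pigment=PigmentSpec(count_mean=2.0),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class CalyxTruth:
    calyx_id: int
    pn_id: int
    coverage_target: float
    coverage_truth: float        # achieved surface-voxel fraction
    n_swellings: int
    axis: tuple[float, float, float]      # cap axis (unit, voxel frame)
    cos_theta: float                      # cap half-angle threshold
    lobe_dirs: list = field(default_factory=list)
    fragmented: bool = False


@dataclass
class PigmentTruth:
    pigment_id: int
    pn_id: int
    diameter_um: float           # achieved equivalent-sphere diameter
    target_diameter_um: float


@dataclass
class PNTruth:
    pn_id: int
    centroid_um: tuple[float, float, float]
    diameter_um: float
    semi_axes_um: tuple[float, float, float]
    exponent: float
    region: str
    clipped: bool
    calyces: list = field(default_factory=list)
    bouton_ids: list = field(default_factory=list)
    pigments: list = field(default_factory=list)
    roughened: bool = False

    @property
    def n_calyces(self) -> int:
        return len(self.calyces)

    @property
    def n_boutons(self) -> int:
        return len(self.bouton_ids)


@dataclass
class GroundTruthManifest:
    seed: int
    pns: list
    region_counts: dict
    region_density_mm3: dict
    volume_mm3: float

    # -- convenience --------------------------------------------------------
    def pn(self, pn_id: int) -> PNTruth:
        for p in self.pns:
            if p.pn_id == pn_id:
                return p
        raise KeyError(pn_id)

    @property
    def n_pn(self) -> int:
        return len(self.pns)

    @property
    def poly_pn_ids(self) -> list[int]:
        return [p.pn_id for p in self.pns if p.n_calyces >= 2]

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        s = json.dumps(d, sort_keys=True, default=_jsonable, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthManifest":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        pns = []
        for p in d["pns"]:
            p = dict(p)
            p["calyces"] = [CalyxTruth(**c) for c in p["calyces"]]
            p["pigments"] = [PigmentTruth(**g) for g in p["pigments"]]
            pns.append(PNTruth(**p))
        return cls(
            seed=d["seed"],
            pns=pns,
            region_counts=d["region_counts"],
            region_density_mm3=d["region_density_mm3"],
            volume_mm3=d["volume_mm3"],
        )


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not jsonable: {type(o)}")


# ---------------------------------------------------------------------------
# geometry helpers (voxel frame; semi-axes per axis in voxels)
# ---------------------------------------------------------------------------

def _radial_field(shape, center_vox, semi_axes_vox, exponent):
    """rho(x): <=1 inside the superellipsoid, ~radial proportion outside."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    g = sum(
        (np.abs(gr - c).astype(np.float32) / np.float32(a)) ** np.float32(exponent)
        for gr, c, a in zip(grids, center_vox, semi_axes_vox)
    )
    return g ** np.float32(1.0 / exponent)


def _surface_radius_vox(v, semi_axes_vox, exponent):
    """Distance from center to the superellipsoid surface along unit v."""
    g = sum((abs(vi) / a) ** exponent for vi, a in zip(v, semi_axes_vox))
    return g ** (-1.0 / exponent)


def _cap_fibonacci_dirs(n, cos_theta, axis, margin_frac=0.12):
    """n directions spread over the spherical cap around ``axis``."""
    if n == 0:
        return []
    lo = cos_theta + margin_frac * (1.0 - cos_theta)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    zz = 1.0 - (1.0 - lo) * (k + 0.5) / n
    th = ga * k
    s = np.sqrt(np.clip(1.0 - zz**2, 0.0, None))
    local = np.c_[s * np.cos(th), s * np.sin(th), zz]
    # rotate +z onto axis
    e1, e2 = _orthonormal(axis)
    R = np.c_[e1, e2, np.asarray(axis)]
    return list(local @ R.T)


def _orthonormal(u):
    u = np.asarray(u, dtype=float)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _paint_ellipsoid(labels, center_vox, radii_vox, value, allow_mask=None):
    """Paint an axis-aligned ellipsoid; returns number of voxels painted."""
    lo = np.maximum(np.floor(center_vox - radii_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center_vox + radii_vox).astype(int) + 2,
                    np.asarray(labels.shape))
    if np.any(lo >= hi):
        return 0
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    d2 = sum(((gr - c) / r) ** 2 for gr, c, r in zip(grids, center_vox, radii_vox))
    m = d2 <= 1.0
    if allow_mask is not None:
        m &= allow_mask[sl]
    else:
        m &= labels[sl] == 0
    labels[sl][m] = value
    return int(m.sum())


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_somas(cfg: SimulationConfig, rng: np.random.Generator):
    """Returns (centers_um (n,3), diameters_um (n,)) or raises PackingError."""
    ext = np.asarray(cfg.volume_shape_um, dtype=float)
    d_lo, d_hi = cfg.soma_diameter_um
    if cfg.n_pn == 0:
        return np.zeros((0, 3)), np.zeros(0)

    if cfg.placement == "line":
        # cells spread along the tonotopic (Y) axis, staggered in X
        margin = d_hi / 2.0 * (1.0 + cfg.eccentricity) + cfg.shell_thickness_um + 0.5
        if cfg.n_pn > 1 and ext[1] - 2 * margin <= 0:
            raise PackingError("volume too short along the tonotopic axis")
        ys = np.linspace(margin, ext[1] - margin, cfg.n_pn) if cfg.n_pn > 1 \
            else np.array([ext[1] / 2.0])
        stagger = max(0.0, min(20.0, (ext[0] / 2.0) - margin)) if cfg.n_pn > 1 else 0.0
        offsets = np.array([-stagger, 0.0, stagger])
        xs = ext[0] / 2.0 + offsets[np.arange(cfg.n_pn) % 3]
        jit = min(1.0, max(0.0, ext[2] / 2.0 - margin))
        zs = np.full(cfg.n_pn, ext[2] / 2.0) + rng.uniform(-jit, jit, cfg.n_pn)
        centers = np.c_[xs + rng.uniform(-jit, jit, cfg.n_pn), ys, zs]
        diams = rng.uniform(d_lo, d_hi, cfg.n_pn)
        dmat = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        need = (diams[:, None] + diams[None]) / 2.0 + 0.5
        if (dmat < need).any():
            raise PackingError(
                f"line placement of {cfg.n_pn} somas (diam <= {d_hi} um) does "
                f"not fit a {tuple(ext)} um volume; enlarge the volume or "
                f"reduce n_pn"
            )
        return centers, diams

    # stratified random sequential placement: per-third cell counts are set
    # exactly (largest remainder) at the LF:HF density gradient, cells are
    # then placed uniformly within their third in a random global order, and
    # overlap exclusion uses the minimum-image (toroidal) metric so that the
    # realized center process is homogeneous (no boundary depletion or
    # wall-excess artifacts of naive rejection sampling)
    lf, hf = cfg.density_gradient
    ratio = lf / hf
    g = 6.0 * (ratio - 1.0) / (5.0 * ratio - 1.0)
    third_w = np.array([1.0 - g / 6.0, 1.0 - g / 2.0, 1.0 - 5.0 * g / 6.0])
    p = third_w / third_w.sum()
    quota = np.floor(cfg.n_pn * p).astype(int)
    rem = cfg.n_pn - quota.sum()
    order_rem = np.argsort(-(cfg.n_pn * p - quota))
    quota[order_rem[:rem]] += 1
    thirds = np.concatenate([np.full(q, k) for k, q in enumerate(quota)])
    rng.shuffle(thirds)

    centers_list: list[np.ndarray] = []
    diam_list: list[float] = []
    c_arr = np.zeros((0, 3))
    d_arr = np.zeros(0)
    y_width = ext[1] / 3.0
    for k in thirds:
        d = float(rng.uniform(d_lo, d_hi))
        placed = False
        for _ in range(4000):
            pos = np.array([
                rng.uniform(0, ext[0]),
                rng.uniform(k * y_width, (k + 1) * y_width),
                rng.uniform(0, ext[2]),
            ])
            if cfg.boundary == "inset":
                r_in = d / 2.0 * (1.0 + cfg.eccentricity) + 1.0
                if np.any(pos < r_in) or np.any(pos > ext - r_in):
                    continue
            if len(c_arr):
                delta = np.abs(c_arr - pos)
                delta = np.minimum(delta, ext - delta)  # minimum image
                need = (d_arr + d) / 2.0 + cfg.min_gap_um
                if np.any(np.linalg.norm(delta, axis=1) < need):
                    continue
            placed = True
            break
        if not placed:
            raise PackingError(
                f"placed only {len(centers_list)}/{cfg.n_pn} somas of "
                f"{d_lo}-{d_hi} um in a {tuple(float(e) for e in ext)} um "
                f"volume (packing too dense); enlarge the volume or reduce n_pn"
            )
        centers_list.append(pos)
        diam_list.append(d)
        c_arr = np.asarray(centers_list)
        d_arr = np.asarray(diam_list)
    return c_arr, d_arr


# ---------------------------------------------------------------------------
# calyx rendering
# ---------------------------------------------------------------------------

def render_calyx(
    labels: np.ndarray,
    pitch_um: np.ndarray,
    pn_id: int,
    calyx_id: int,
    center_vox: np.ndarray,
    semi_axes_vox: np.ndarray,
    exponent: float,
    coverage: float,
    n_swellings: int,
    axis_dir: np.ndarray,
    shell_thickness_um: float,
    lobe_radius_um: float,
    axon_radius_um: float,
    excluded_cos: Optional[list] = None,
    clamp_swellings: bool = False,
) -> CalyxTruth:
    """Paint one calyx (shell sector + axon cone + swelling lobes).

    The cap footprint is calibrated on the soma's *surface voxels*: the cap
    half-angle is the quantile of surface-voxel angles around ``axis_dir``
    that makes the covered surface fraction equal ``coverage``; the achieved
    fraction (the ground truth) is recorded from a brute surface-voxel count.
    Swellings are ``n_swellings`` spherical lobes (radius >= 2x shell
    thickness) attached outside the shell on a Fibonacci layout; a thin axon
    cone leaves the cap pole.  Raises :class:`PackingError` for coverage
    >= 0.95 (a polar gap is reserved for the axon cone) or if the lobes
    cannot be packed without merging.
    """
    if not (0.0 < coverage < 0.95):
        raise PackingError(
            f"coverage target {coverage} outside (0, 0.95); the polar gap is "
            f"reserved for the axon cone"
        )
    if n_swellings < 0:
        raise ValueError("n_swellings must be >= 0")
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)

    shell_vox = shell_thickness_um / pitch_um          # per-axis thickness
    lobe_vox = lobe_radius_um / pitch_um
    reach = int(np.ceil(shell_vox.max() + 2 * lobe_vox.max())) + 3
    lo = np.maximum((center_vox - semi_axes_vox).astype(int) - reach, 0)
    hi = np.minimum((center_vox + semi_axes_vox).astype(int) + reach + 1,
                    np.asarray(labels.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = labels[sl]
    c_loc = center_vox - lo

    rho = _radial_field(sub.shape, c_loc, semi_axes_vox, exponent)
    soma = sub == pn_id
    if not soma.any():
        raise ValueError(f"PN {pn_id} empty in calyx crop")

    grids = np.ogrid[tuple(slice(0, s) for s in sub.shape)]
    rel = [((gr - c) * p).astype(np.float32)
           for gr, c, p in zip(grids, c_loc, pitch_um)]
    rr = np.sqrt(sum(r * r for r in rel))
    cosang = sum(r * np.float32(a) for r, a in zip(rel, axis_dir)) \
        / np.maximum(rr, np.float32(1e-9))

    surf = surface_voxels(soma)
    cos_surf = cosang[surf]
    avail = np.ones(cos_surf.shape, bool)
    if excluded_cos is not None:
        for other_axis, other_cos in excluded_cos:
            oc = sum(r * a for r, a in zip(rel, np.asarray(other_axis)))
            oc = (oc / np.maximum(rr, 1e-9))[surf]
            avail &= oc < other_cos
    if avail.mean() <= coverage + 0.02:
        raise PackingError(
            f"coverage {coverage} does not fit next to existing caps on PN {pn_id}"
        )
    # threshold on the available surface so the achieved total fraction of the
    # WHOLE surface equals the target
    k = int(round(coverage * cos_surf.size))
    order = np.sort(cos_surf[avail])[::-1]
    if k < 1 or k > order.size:
        raise PackingError(f"coverage {coverage} unachievable on PN {pn_id}")
    cos_thr = float(order[k - 1])

    # foreign structures must stay non-adjacent (no spurious contact edges)
    foreign = (sub != 0) & (sub != pn_id)
    forbidden = ndi.binary_dilation(foreign, structure=_SIX_CONN)
    free = (sub == 0) & ~forbidden

    outer_axes = semi_axes_vox + shell_vox
    rho_out = _radial_field(sub.shape, c_loc, outer_axes, exponent)
    shell = (rho > 1.0) & (rho_out <= 1.0) & (cosang >= cos_thr) & free
    if excluded_cos is not None:
        for other_axis, other_cos in excluded_cos:
            oc = sum(r * a for r, a in zip(rel, np.asarray(other_axis)))
            shell &= (oc / np.maximum(rr, 1e-9)) < other_cos
    sub[shell] = calyx_id

    # axon cone: a thin tube leaving the cap pole outward
    t_par = sum(r * a for r, a in zip(rel, axis_dir))
    perp = np.sqrt(np.clip(rr**2 - t_par**2, 0.0, None))
    r_pole = _surface_radius_vox(axis_dir, semi_axes_vox, exponent) * pitch_um.mean()
    tube_len = shell_thickness_um + 2.0 * lobe_radius_um
    tube = (
        (t_par > r_pole * 0.9)
        & (t_par <= r_pole + tube_len)
        & (perp <= axon_radius_um)
        & free
        & (rho > 1.0)
    )
    sub[tube] = calyx_id

    # swelling lobes
    if clamp_swellings:
        n_swellings = _max_feasible_swellings(
            n_swellings, cos_thr, axis_dir, semi_axes_vox, exponent,
            shell_thickness_um, lobe_radius_um, pitch_um,
        )
    lobe_dirs = _cap_fibonacci_dirs(n_swellings, cos_thr, axis_dir)
    if n_swellings:
        centers = []
        for v in lobe_dirs:
            r_s = _surface_radius_vox(v, semi_axes_vox, exponent)
            step_vox = (shell_thickness_um + 0.55 * lobe_radius_um) / pitch_um
            centers.append(c_loc + v * (r_s + np.linalg.norm(step_vox) / np.sqrt(3)))
        centers = np.asarray(centers)
        if len(centers) > 1:
            dmat = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
            np.fill_diagonal(dmat, np.inf)
            min_sep = 2.0 * lobe_vox.max() + 3.0
            if dmat.min() < min_sep:
                raise PackingError(
                    f"{n_swellings} swellings do not fit on a cap of coverage "
                    f"{coverage:.2f} without merging (min separation "
                    f"{dmat.min():.1f} < {min_sep:.1f} vox); raise coverage or "
                    f"lower n_swellings"
                )
        # keep lobes clear of the axon cone
        for i, v in enumerate(lobe_dirs):
            if float(np.dot(v, axis_dir)) > 0.985:
                raise PackingError("swelling lobe collides with the axon cone")
        # paint; a lobe blocked by a foreign structure (or the volume edge)
        # would be undercounted downstream, so it is unpainted and dropped
        # (clamped mode) or raises
        full_ball = (4.0 / 3.0) * np.pi * float(np.prod(lobe_vox))
        soma_block = soma | forbidden
        kept_dirs = []
        for ctr, v in zip(centers, lobe_dirs):
            lo_l = np.maximum(np.floor(ctr - lobe_vox).astype(int) - 1, 0)
            hi_l = np.minimum(np.ceil(ctr + lobe_vox).astype(int) + 2,
                              np.asarray(sub.shape))
            sll = tuple(slice(a, b) for a, b in zip(lo_l, hi_l))
            g2 = np.ogrid[tuple(slice(a, b) for a, b in zip(lo_l, hi_l))]
            d2 = sum(((gr - cc) / rv) ** 2 for gr, cc, rv in zip(g2, ctr, lobe_vox))
            m = (d2 <= 1.0) & ~soma_block[sll] & (sub[sll] == 0)
            if int(m.sum()) < 0.60 * full_ball:
                if not clamp_swellings:
                    raise PackingError(
                        f"swelling lobe of calyx {calyx_id} blocked by a "
                        f"neighboring structure or the volume boundary"
                    )
                continue
            sub[sll][m] = calyx_id
            kept_dirs.append(v)
        lobe_dirs = kept_dirs
        n_swellings = len(kept_dirs)

    # achieved coverage: brute surface-voxel count against the painted calyx
    near = ndi.binary_dilation(sub == calyx_id, structure=np.ones((3, 3, 3), bool))
    truth = float((surf & near).sum()) / float(surf.sum())

    return CalyxTruth(
        calyx_id=calyx_id,
        pn_id=pn_id,
        coverage_target=float(coverage),
        coverage_truth=truth,
        n_swellings=int(n_swellings),
        axis=tuple(float(a) for a in axis_dir),
        cos_theta=cos_thr,
        lobe_dirs=[tuple(float(x) for x in v) for v in lobe_dirs],
    )


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _resolve_per_item(spec, n, rng, integer=False):
    """None | (lo, hi) tuple = random range | list/array = per-item values."""
    if spec is None:
        return None
    if isinstance(spec, tuple):
        if len(spec) != 2:
            raise ValueError("range spec must be a (lo, hi) tuple")
        lo, hi = spec
        if integer:
            return rng.integers(int(lo), int(hi) + 1, n)
        return rng.uniform(lo, hi, n)
    arr = np.asarray(spec, dtype=int if integer else float)
    if arr.size != n:
        raise ValueError(f"expected {n} per-item values, got {arr.size}")
    return arr


def generate_dataset(cfg: SimulationConfig):
    """Render a synthetic scene.

    Returns ``(volume, segment_table, manifest)``; deterministic under
    ``cfg.seed``.  Degeneration, when configured, is applied in-place via
    :func:`apply_degeneration` before the table is derived.
    """
    rng = np.random.default_rng(cfg.seed)
    pitch_um = np.asarray(cfg.voxel_pitch_nm, dtype=float) / 1000.0
    ext = np.asarray(cfg.volume_shape_um, dtype=float)
    shape = tuple(int(round(e / p)) for e, p in zip(ext, pitch_um))
    labels = np.zeros(shape, dtype=np.int32)
    volume = AnnotatedVolume(labels=labels, voxel_pitch_nm=tuple(cfg.voxel_pitch_nm))
    frame = TonotopicFrame.from_volume(volume)

    centers_um, diams_um = _place_somas(cfg, rng)
    n = len(centers_um)
    coverages = _resolve_per_item(cfg.coverage_targets, n, rng)
    poly = rng.random(n) < cfg.poly_fraction if cfg.poly_fraction > 0 else np.zeros(n, bool)
    n_calyx_total = n + int(poly.sum()) if coverages is not None else 0
    swell = _resolve_per_item(cfg.swelling_counts, n_calyx_total, rng, integer=True)

    pns: list[PNTruth] = []
    soma_geom = {}
    # a superellipsoid with exponent e > 2 encloses more volume than the
    # sphere of the same semi-axes; normalize so the rendered body has the
    # equivalent-sphere diameter the manifest promises
    from scipy.special import gamma as _gamma

    e = cfg.superellipsoid_exponent
    vol_frac = _gamma(1.0 + 1.0 / e) ** 3 / _gamma(1.0 + 3.0 / e)
    shape_scale = (np.pi / 6.0 / vol_frac) ** (1.0 / 3.0)
    # ---- somas ----
    for i in range(n):
        pn_id = PN_ID_BASE + i
        c_vox = centers_um[i] / pitch_um
        semi_um = (diams_um[i] / 2.0) * shape_scale * (
            1.0 + rng.uniform(-cfg.eccentricity, cfg.eccentricity, 3))
        semi_vox = semi_um / pitch_um
        lo = np.maximum(np.floor(c_vox - semi_vox).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(c_vox + semi_vox).astype(int) + 2, np.asarray(shape))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        rho = _radial_field(labels[sl].shape, c_vox - lo, semi_vox,
                            cfg.superellipsoid_exponent)
        m = (rho <= 1.0) & (labels[sl] == 0)
        labels[sl][m] = pn_id
        clipped = bool(
            np.any(c_vox - semi_vox < 0) or np.any(c_vox + semi_vox > np.asarray(shape))
        )
        region = frame.region_of(float(np.clip(centers_um[i][1], 0, ext[1])))
        pns.append(
            PNTruth(
                pn_id=pn_id,
                centroid_um=tuple(float(x) for x in centers_um[i]),
                diameter_um=float(diams_um[i]),
                semi_axes_um=tuple(float(x) for x in semi_um),
                exponent=float(cfg.superellipsoid_exponent),
                region=region,
                clipped=clipped,
            )
        )
        soma_geom[pn_id] = (c_vox, semi_vox)

    # ---- calyces ----
    calyx_id = CALYX_ID_BASE
    k_sw = 0
    if coverages is not None:
        phase_axes = (np.array([-1.0, 0, 0]), np.array([0, 0, 1.0]),
                      np.array([1.0, 0, 0]))
        for i, pn in enumerate(pns):
            c_vox, semi_vox = soma_geom[pn.pn_id]
            caps = [float(coverages[i])]
            if poly[i]:
                caps.append(float(rng.uniform(*cfg.secondary_coverage)))
            excluded = []
            if cfg.placement == "line":
                pref = phase_axes[i % 3].copy()
                if i % 3 == 1 and (i // 3) % 2:
                    pref = -pref
            else:
                pref = None
            for j, cap_cov in enumerate(caps):
                preferred = pref if j == 0 or pref is None else -pref
                axis_dir = _random_cap_axis(cfg, rng, excluded, preferred)
                n_sw = int(swell[k_sw]) if swell is not None else 0
                truth = render_calyx(
                    labels, pitch_um, pn.pn_id, calyx_id, c_vox, semi_vox,
                    cfg.superellipsoid_exponent, cap_cov, n_sw, axis_dir,
                    cfg.shell_thickness_um, cfg.lobe_radius_um,
                    cfg.axon_radius_um,
                    excluded_cos=excluded or None,
                    clamp_swellings=isinstance(cfg.swelling_counts, tuple),
                )
                pn.calyces.append(truth)
                excluded.append((np.asarray(truth.axis), truth.cos_theta - 0.08))
                calyx_id += 1
                k_sw += 1

    # ---- boutons ----
    if cfg.boutons is not None:
        bouton_id = BOUTON_ID_BASE
        for pn in pns:
            mean = cfg.boutons.lf_mean + (cfg.boutons.hf_mean - cfg.boutons.lf_mean) \
                * (pn.centroid_um[1] / ext[1])
            n_b = int(rng.poisson(mean))
            placed = _place_boutons(labels, pitch_um, pn, soma_geom[pn.pn_id],
                                    cfg, n_b, bouton_id, rng)
            pn.bouton_ids = placed
            bouton_id += len(placed)

    # ---- pigments ----
    if cfg.pigment is not None:
        pigment_id = PIGMENT_ID_BASE
        for pn in pns:
            spots = _place_pigments(labels, pitch_um, pn, soma_geom[pn.pn_id],
                                    cfg, pigment_id, rng)
            pn.pigments = spots
            pigment_id += len(spots)

    # ---- manifest ----
    region_counts = {r: 0 for r in ("lateral", "central", "medial")}
    for pn in pns:
        region_counts[pn.region] += 1
    vol_mm3 = float(np.prod(ext)) * 1e-9
    region_density = {}
    for r in region_counts:
        a, b = frame.region_interval_um(r)
        slab_mm3 = (b - a) * ext[0] * ext[2] * 1e-9
        region_density[r] = region_counts[r] / slab_mm3
    manifest = GroundTruthManifest(
        seed=cfg.seed,
        pns=pns,
        region_counts=region_counts,
        region_density_mm3=region_density,
        volume_mm3=vol_mm3,
    )

    if cfg.degeneration is not None:
        apply_degeneration(volume, manifest, cfg.degeneration,
                           rng=np.random.default_rng(cfg.seed + 101))

    table = _build_table(volume, manifest)
    return volume, table, manifest


def _max_feasible_swellings(n, cos_thr, axis_dir, semi_axes_vox, exponent,
                            shell_um, lobe_um, pitch_um) -> int:
    """Largest count <= n whose Fibonacci lobe layout keeps lobes separate."""
    lobe_vox = lobe_um / pitch_um
    min_sep = 2.0 * lobe_vox.max() + 3.0
    step = np.linalg.norm((shell_um + 0.55 * lobe_um) / pitch_um) / np.sqrt(3)
    while n > 1:
        centers = []
        for v in _cap_fibonacci_dirs(n, cos_thr, axis_dir):
            r_s = _surface_radius_vox(v, semi_axes_vox, exponent)
            centers.append(v * (r_s + step))
        centers = np.asarray(centers)
        dmat = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() >= min_sep and all(
            float(np.dot(v, axis_dir)) <= 0.985
            for v in _cap_fibonacci_dirs(n, cos_thr, axis_dir)
        ):
            return n
        n -= 1
    return n


def _random_cap_axis(cfg, rng, excluded, preferred=None):
    """Cap axis; in line placement caps are steered toward the free space on
    each cell's open side (phase-dependent preferred direction) so that
    shells and swelling lobes do not collide with neighboring cells."""
    for trial in range(300):
        if preferred is not None:
            v = np.asarray(preferred) + (0.25 + 0.002 * trial) * rng.normal(size=3)
        else:
            v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if cfg.placement == "line" and abs(v[1]) > 0.35:
            continue
        ok = True
        for other_axis, other_cos in excluded:
            sep_needed = np.arccos(np.clip(other_cos, -1, 1)) + \
                np.arccos(1 - 2 * 0.25) * 0.9
            if np.arccos(np.clip(np.dot(v, other_axis), -1, 1)) < sep_needed:
                ok = False
                break
        if ok:
            return v
    raise PackingError("could not orient a second calyx cap away from the first")


def _place_boutons(labels, pitch_um, pn, geom, cfg, n_b, id_base, rng):
    c_vox, semi_vox = geom
    spec = cfg.boutons
    b_r_vox = spec.radius_um / pitch_um
    r_mean_um = float(np.mean(semi_vox * pitch_um))
    min_ang = 2.3 * spec.radius_um / r_mean_um
    cap_margin = spec.radius_um * 1.5 / r_mean_um
    caps = [(np.asarray(c.axis), c.cos_theta) for c in pn.calyces]

    # forbid adjacency to other PNs' somas (no spurious contacts)
    reach = int(np.ceil(semi_vox.max() + 2 * b_r_vox.max())) + 3
    lo = np.maximum((c_vox - reach).astype(int), 0)
    hi = np.minimum((c_vox + reach).astype(int) + 1, np.asarray(labels.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = labels[sl]
    foreign = (sub >= PN_ID_BASE) & (sub < CALYX_ID_BASE) & (sub != pn.pn_id)
    allow = (sub == 0) & ~ndi.binary_dilation(foreign, structure=_SIX_CONN)

    placed = []
    dirs: list[np.ndarray] = []
    tries = 0
    next_id = id_base
    while len(placed) < n_b and tries < 80 * max(n_b, 1):
        tries += 1
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        bad = False
        for axis, cth in caps:
            if float(np.dot(v, axis)) >= cth - cap_margin:
                bad = True
                break
        if bad:
            continue
        if any(float(np.dot(v, u)) > np.cos(min_ang) for u in dirs):
            continue
        r_s = _surface_radius_vox(v, semi_vox, cfg.superellipsoid_exponent)
        ctr = (c_vox - lo) + v * r_s
        n_painted = _paint_ellipsoid(sub, ctr, b_r_vox, next_id, allow_mask=allow)
        if n_painted < 4:
            sub[sub == next_id] = 0
            continue
        dirs.append(v)
        placed.append(next_id)
        next_id += 1
    if n_b and len(placed) < n_b:
        warnings.warn(
            f"PN {pn.pn_id}: placed {len(placed)}/{n_b} boutons (surface full)"
        )
    return placed


def _place_pigments(labels, pitch_um, pn, geom, cfg, id_base, rng):
    c_vox, semi_vox = geom
    spec = cfg.pigment
    n_s = int(rng.poisson(spec.count_mean))
    spots: list[PigmentTruth] = []
    existing: list[tuple[np.ndarray, float]] = []
    vox_vol = float(np.prod(pitch_um))
    next_id = id_base
    tries = 0
    while len(spots) < n_s and tries < 60 * max(n_s, 1):
        tries += 1
        target_d = float(np.clip(
            rng.lognormal(np.log(spec.diam_gm_um), spec.diam_log_sigma),
            spec.min_diam_um, spec.max_diam_um,
        ))
        p_r_vox = (target_d / 2.0) / pitch_um
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        max_rho = 1.0 - (p_r_vox.max() + 2.0) / semi_vox.min()
        if max_rho <= 0.05:
            continue
        rho_c = rng.random() ** (1.0 / 3.0) * max_rho
        r_s = _surface_radius_vox(v, semi_vox, cfg.superellipsoid_exponent)
        ctr = c_vox + v * (rho_c * r_s)
        if any(np.linalg.norm(ctr - e_c) < e_r + p_r_vox.max() + 1.5
               for e_c, e_r in existing):
            continue
        lo = np.maximum(np.floor(ctr - p_r_vox).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(ctr + p_r_vox).astype(int) + 2,
                        np.asarray(labels.shape))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        g2 = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
        d2 = sum(((gr - cc) / rv) ** 2 for gr, cc, rv in zip(g2, ctr, p_r_vox))
        m = (d2 <= 1.0) & (labels[sl] == pn.pn_id)
        count = int(m.sum())
        if count == 0:
            continue
        labels[sl][m] = next_id
        achieved_d = float((6.0 * count * vox_vol / np.pi) ** (1.0 / 3.0))
        spots.append(PigmentTruth(
            pigment_id=next_id, pn_id=pn.pn_id,
            diameter_um=achieved_d, target_diameter_um=target_d,
        ))
        existing.append((ctr, float(p_r_vox.max())))
        next_id += 1
    return spots


def _build_table(volume: AnnotatedVolume, manifest: GroundTruthManifest):
    class_map = {}
    for pn in manifest.pns:
        class_map[pn.pn_id] = SegmentClass.PN_SOMA
        for c in pn.calyces:
            class_map[c.calyx_id] = SegmentClass.CALYX
        for b in pn.bouton_ids:
            class_map[b] = SegmentClass.NONCALYCEAL
        for g in pn.pigments:
            class_map[g.pigment_id] = SegmentClass.PIGMENT
    return derive_segment_table(volume, class_map)


# ---------------------------------------------------------------------------
# degeneration
# ---------------------------------------------------------------------------

def apply_degeneration(
    volume: AnnotatedVolume,
    manifest: GroundTruthManifest,
    spec: DegenerationSpec,
    rng: np.random.Generator | None = None,
):
    """Mutate a rendered scene: fragment calyces and roughen PN membranes.

    Fragmentation removes the cap pole (detaching the axon cone) and cuts
    >= 3 azimuthal wedges through the shell, chosen in the gaps between
    swelling lobes, until the calyx label falls into >= 3 connected
    components.  Roughening carves correlated radial dips (depth up to
    ``rough_amplitude`` x radius) into the soma boundary, which raises its
    boundary-roughness score above intact controls.  Manifest flags are
    updated in place; the (volume, manifest) pair is returned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    all_calyces = [c for pn in manifest.pns for c in pn.calyces]
    n_frag = int(round(spec.ch_fragment_fraction * len(all_calyces)))
    if n_frag:
        idx = rng.choice(len(all_calyces), size=n_frag, replace=False)
        for i in idx:
            _fragment_calyx(volume.labels, all_calyces[i], rng)
            all_calyces[i].fragmented = True
    n_rough = int(round(spec.pn_rough_fraction * len(manifest.pns)))
    if n_rough:
        idx = rng.choice(len(manifest.pns), size=n_rough, replace=False)
        pitch_um = volume.pitch_um
        for i in idx:
            _roughen_pn(volume.labels, pitch_um, manifest.pns[i], spec, rng)
            manifest.pns[i].roughened = True
    return volume, manifest


def _fragment_calyx(labels, truth: CalyxTruth, rng, min_pieces: int = 3):
    mask = labels == truth.calyx_id
    if not mask.any():
        return
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = labels[sl]
    m = sub == truth.calyx_id
    axis = np.asarray(truth.axis)
    # geometry around the cap centroid projected back toward the soma center
    pts = np.argwhere(m).astype(float)
    centroid = pts.mean(axis=0)
    depth = pts - centroid
    # center of the host sphere approx: centroid - axis * mean radial extent
    r_guess = np.abs(depth @ axis).max() + np.linalg.norm(depth, axis=1).mean()
    center = centroid - axis * r_guess * 0.6
    rel = pts - center
    rn = np.linalg.norm(rel, axis=1)
    cosang = (rel @ axis) / np.maximum(rn, 1e-9)
    theta = np.arccos(np.clip(truth.cos_theta, -1, 1))
    e1, e2 = _orthonormal(axis)
    phi = np.arctan2(rel @ e2, rel @ e1)
    lobe_phi = []
    for v in truth.lobe_dirs:
        v = np.asarray(v)
        lobe_phi.append(float(np.arctan2(v @ e2, v @ e1)))

    for attempt in range(6):
        drop = cosang > np.cos(theta * (0.30 + 0.05 * attempt))  # polar disc
        n_cuts = min_pieces + attempt % 2
        phase = rng.uniform(0, 2 * np.pi)
        width = (0.10 + 0.03 * attempt)
        for k in range(n_cuts):
            phi_c = phase + 2 * np.pi * k / n_cuts
            if lobe_phi:
                # nudge the cut into the widest gap near this azimuth
                diffs = [abs(np.angle(np.exp(1j * (phi_c - lp)))) for lp in lobe_phi]
                if min(diffs) < width + 0.15:
                    phi_c += (width + 0.2)
            d = np.abs(np.angle(np.exp(1j * (phi - phi_c))))
            drop |= d < width
        trial = m.copy()
        trial[tuple(pts[drop].astype(int).T)] = False
        _, n_comp = ndi.label(trial, structure=_SIX_CONN)
        if n_comp >= min_pieces:
            sub[tuple(pts[drop].astype(int).T)] = 0
            return
    raise PackingError(
        f"could not fragment calyx {truth.calyx_id} into >= {min_pieces} pieces"
    )


def _roughen_pn(labels, pitch_um, pn: PNTruth, spec: DegenerationSpec, rng):
    semi_vox = np.asarray(pn.semi_axes_um) / pitch_um
    c_vox = np.asarray(pn.centroid_um) / pitch_um
    lo = np.maximum(np.floor(c_vox - semi_vox).astype(int) - 2, 0)
    hi = np.minimum(np.ceil(c_vox + semi_vox).astype(int) + 3,
                    np.asarray(labels.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = labels[sl]
    rho = _radial_field(sub.shape, c_vox - lo, semi_vox, pn.exponent)
    noise = ndi.gaussian_filter(rng.standard_normal(sub.shape), spec.rough_sigma_vox)
    noise /= max(noise.std(), 1e-9)
    carve = (sub == pn.pn_id) & (rho > 1.0 - spec.rough_amplitude
                                 * np.clip(noise, 0.0, None))
    sub[carve] = 0


# ---------------------------------------------------------------------------
# brute-force recounts (oracle helpers used by tests and the manifest check)
# ---------------------------------------------------------------------------

def surface_coverage_oracle(labels, pn_id, calyx_id) -> float:
    """Fraction of PN surface voxels within one voxel of the calyx label.

    Independent of the dilation-shell measurement: counts boundary voxels of
    the soma whose 26-neighborhood contains the calyx id.  Intracellular
    cavities (pigment granules carved from the soma label) are filled so the
    surface is the outer membrane.
    """
    mask = ndi.binary_fill_holes(labels == pn_id)
    surf = surface_voxels(mask)
    near = ndi.binary_dilation(labels == calyx_id,
                               structure=np.ones((3, 3, 3), bool))
    return float((surf & near).sum()) / float(surf.sum())
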