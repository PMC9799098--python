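"""End-to-end orchestration: simulate/load -> measure -> summarize -> report.

``run_pipeline`` executes every analysis stage on one scene (a synthetic
scene generated from a preset, or a volume + segment table loaded from
disk), writes CSV tables plus a JSON summary, and logs every radius,
threshold and seed used.  Reruns with the same configuration and seed
produce byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import degeneration as deg
from . import innervation as inn
from . import stereology as ste
from .io import write_frame, write_segment_table, write_volume
from .model import AnnotatedVolume, SegmentClass, TonotopicFrame
from .synthetic import GroundTruthManifest, SimulationConfig, generate_dataset


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """What to run and with which parameters.

    Either ``preset``/``simulation`` (synthetic scene) or ``volume_path`` +
    ``table_path`` must be given; a frame is derived from the volume when not
    supplied.
    """

    out_dir: str = "calyxmorph_out"
    seed: int = 0
    preset: str | None = "tiny"
    simulation: SimulationConfig | None = None
    volume_path: str | None = None
    table_path: str | None = None
    frame: TonotopicFrame | None = None
    r_soma: int = cov.DEFAULT_R_SOMA
    r_axon: int = cov.DEFAULT_R_AXON
    r_guard: int = cov.DEFAULT_R_GUARD
    min_contact_voxels: int = inn.DEFAULT_MIN_CONTACT_VOXELS
    opening_radius_um: float = inn.DEFAULT_OPENING_RADIUS_UM
    roughness_threshold: float = deg.ROUGHNESS_THRESHOLD
    cube_side_um: float = ste.CUBE_SIDE_UM
    n_cubes: int = 4
    run_stereology: bool = True
    save_volume: bool = False

    def resolve_simulation(self) -> SimulationConfig | None:
        if self.simulation is not None:
            return self.simulation
        if self.preset is None:
            return None
        presets = {
            "tiny": SimulationConfig.tiny,
            "morphometry": SimulationConfig.morphometry,
            "stereology": SimulationConfig.stereology,
            "degeneration": SimulationConfig.degeneration_preset,
        }
        if self.preset not in presets:
            raise PipelineConfigError(
                f"unknown preset {self.preset!r}; choose from {sorted(presets)}"
            )
        return presets[self.preset](seed=self.seed)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(msg)

    sim = cfg.resolve_simulation()
    manifest: GroundTruthManifest | None = None
    if sim is not None:
        sim_cfg = sim if sim.seed == cfg.seed else _with_seed(sim, cfg.seed)
        log(f"simulate: preset={cfg.preset} seed={sim_cfg.seed}")
        volume, table, manifest = generate_dataset(sim_cfg)
        manifest.to_json(out / "manifest.json")
    elif cfg.volume_path and cfg.table_path:
        from .io import read_segment_table, read_volume

        volume = read_volume(cfg.volume_path)
        table = read_segment_table(cfg.table_path)
        log(f"load: volume={cfg.volume_path} table={cfg.table_path}")
    else:
        raise PipelineConfigError(
            "config must name a simulation preset or volume_path + table_path"
        )

    frame = cfg.frame or TonotopicFrame.from_volume(volume)
    write_frame(frame, out / "frame.json")
    write_segment_table(table, out / "segments.csv")
    if cfg.save_volume:
        write_volume(volume, out / "volume.h5")
    log(f"frame: bounds={frame.region_bounds_um} axis={frame.axis}")
    log(f"radii: r_soma={cfg.r_soma} r_axon={cfg.r_axon} r_guard={cfg.r_guard} (voxels)")
    log(f"contacts: min_contact_voxels={cfg.min_contact_voxels}")
    log(f"swellings: opening_radius_um={cfg.opening_radius_um}")
    log(f"degeneration: roughness_threshold={cfg.roughness_threshold}")

    summary: dict = {"seed": cfg.seed, "stages": {}}

    # ---- innervation ----
    try:
        graph = inn.build_contact_graph(volume, table, cfg.min_contact_voxels)
        morphs = inn.calyx_morphologies(volume, table, graph, cfg.opening_radius_um)
    except Exception as e:  # noqa: BLE001 - stage-named diagnostics
        raise RuntimeError(f"innervation stage failed: {e}") from e
    pn_ids = sorted(int(i) for i in graph.per_pn["pn_id"])
    centroid_y = dict(zip(table["segment_id"].astype(int), table["centroid_y_um"]))
    regions = {p: frame.region_of(float(centroid_y[p])) for p in pn_ids}
    k, n, pct = inn.poly_fraction(graph)
    split = inn.regional_poly_split(graph, regions)
    summary["stages"]["innervation"] = {
        "n_pn": n,
        "poly": {"k": k, "n": n, "percent": pct},
        "regional_poly_split": {kk: list(v) for kk, v in split.items()},
        "noncalyceal_per_pn": {
            str(p): inn.count_noncalyceal(graph, p) for p in pn_ids
        },
        "swellings": {str(m.ch_id): m.n_swellings for m in morphs},
        "calyx_types": {str(m.ch_id): m.calyx_type for m in morphs},
    }
    graph.edges.to_csv(out / "contact_edges.csv", index=False)

    # ---- coverage ----
    try:
        cov_rows = []
        for _, row in graph.per_pn.iterrows():
            if not row["calyx_ids"]:
                continue
            res = cov.measure_pn_coverage(
                volume, int(row["pn_id"]), row["calyx_ids"],
                r_soma=cfg.r_soma, r_axon=cfg.r_axon, r_guard=cfg.r_guard,
            )
            cov_rows.append(dict(
                pn_id=res.pn_id, total_fraction=res.total_fraction,
                union_fraction=res.union_fraction, overlap=res.overlap_flag,
                **{f"calyx_{c}": f for c, f in res.per_calyx.items()},
            ))
        cov_df = pd.DataFrame(cov_rows)
        cov_df.to_csv(out / "coverage.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"coverage stage failed: {e}") from e
    summary["stages"]["coverage"] = {
        str(int(r["pn_id"])): round(float(r["total_fraction"]), 6)
        for _, r in cov_df.iterrows()
    } if len(cov_df) else {}

    # ---- stereology ----
    if cfg.run_stereology:
        try:
            ext = volume.extent_um
            side = min(cfg.cube_side_um,
                       float(np.min([ext[0], ext[2],
                                     (frame.medial_end_um - frame.lateral_end_um) / 3.0]))
                       * 0.9)
            dens = ste.regional_density(
                volume, pn_ids, frame, n_cubes=cfg.n_cubes, side_um=side,
                rng=np.random.default_rng(cfg.seed + 7),
            )
            log(f"stereology: cube_side_um={side} n_cubes={cfg.n_cubes}")
            whole = ste.total_density(len(pn_ids), float(np.prod(ext)) * 1e-9)
            lf, hf = ste.regional_percent(dens["lateral"].density_mm3,
                                          dens["medial"].density_mm3) \
                if (dens["lateral"].mean_count + dens["medial"].mean_count) > 0 \
                else (float("nan"), float("nan"))
            summary["stages"]["stereology"] = {
                "whole_density_mm3": whole,
                "cube_side_um": side,
                "regional": {r: {"counts": d.cube_counts,
                                 "density_mm3": d.density_mm3}
                             for r, d in dens.items()},
                "lf_hf_percent": [lf, hf],
            }
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"stereology stage failed: {e}") from e

    # ---- degeneration / pigments ----
    try:
        spots = deg.detect_pigment_spots(volume, table)
        spots.to_csv(out / "pigments.csv", index=False)
        assessments = []
        for p in pn_ids:
            assessments.append(deg.assess_structure(
                volume, p, SegmentClass.PN_SOMA, cfg.roughness_threshold,
                region=regions[p]))
        for _, row in graph.per_pn.iterrows():
            for cid in row["calyx_ids"]:
                assessments.append(deg.assess_structure(
                    volume, int(cid), SegmentClass.CALYX,
                    cfg.roughness_threshold,
                    region=regions[int(row["pn_id"])]))
        deg_summary = deg.degeneration_summary(assessments)
        deg_summary.to_csv(out / "degeneration.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"degeneration stage failed: {e}") from e
    summary["stages"]["degeneration"] = {
        "n_spots_reported": int((spots["size_bin"] != "SUB").sum()) if len(spots) else 0,
        "spots_per_bin": {b: int((spots["size_bin"] == b).sum()) if len(spots) else 0
                          for b in deg.REPORTED_BINS},
        "percent_degenerate": {
            f"{r['klass']}": round(float(r["percent"]), 6)
            for _, r in deg_summary.iterrows() if r["region"] == "ALL"
        },
    }

    # ---- statistics on coverage vs tonotopic position ----
    if len(cov_df) >= 3:
        from .stats import tonotopic_regression

        ys = [centroid_y[int(p)] for p in cov_df["pn_id"]]
        try:
            r2, slope = tonotopic_regression(ys, 100.0 * cov_df["total_fraction"])
            summary["stages"]["tonotopic_regression"] = {
                "r_squared": r2, "slope_pp_per_um": slope,
            }
        except ValueError:
            pass

    summary = _round_floats(summary)
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _with_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)
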