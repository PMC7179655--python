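"""End-to-end orchestration: run a full alanine scan and emit report tables.

The report bundle mirrors the shapes a binding-selectivity study needs:
overall binding summary, per-residue scan table sorted by ΔΔG, hot-spot
list, hydrogen-bond occupancy survey, RMSD / B-factor / 2D-RMSD series, and
a machine-readable JSON run log. ``compare_runs`` pairs residues between two
bundles and flags significant differences with Welch's t-test on
window-level statistics.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .alanine import (
    DdGRecord,
    binding_summary,
    classify_hotspots,
    residue_sum_summary,
    scan_residue,
    total_binding_energy,
)
from .constants import DEFAULT_TEMPERATURE, HOTSPOT_THRESHOLD
from .entropy import WindowPlan, plan_windows
from .errors import ConfigError
from .params import attach_parameters, read_parameter_table
from .system import (
    ParamSystem,
    Trajectory,
    load_trajectory_pdb,
    load_trajectory_text,
    read_structure,
    select_pocket,
)
from .trajtools import bfactor, rmsd_matrix, rmsd_series, hbond_occupancy

__all__ = ["RunConfig", "run_scan", "compare_runs", "compare_tables",
           "records_to_frame"]


@dataclass
class RunConfig:
    """Configuration of a full scan (TOML-loadable)."""

    structure: str = ""
    trajectories: list[str] = field(default_factory=list)
    parameters: str = ""
    output_dir: str = "scan_output"
    ligand_resname: str | None = None
    temperature: float = DEFAULT_TEMPERATURE
    pocket_cutoff: float = 5.0
    hotspot_threshold: float = HOTSPOT_THRESHOLD
    window_length_ps: float = 5000.0
    n_windows_per_replicate: int = 5
    enthalpy_frames_per_window: int = 100
    outlier_k_sd: float = 3.0
    sasa_points: int = 240
    frame_interval_ps: float = 1.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if not self.structure or not Path(self.structure).exists():
            raise ConfigError(f"structure path missing: {self.structure!r}")
        if not self.trajectories:
            raise ConfigError("at least one trajectory path required")
        for t in self.trajectories:
            if not Path(t).exists():
                raise ConfigError(f"trajectory path missing: {t!r}")
        if self.parameters and not Path(self.parameters).exists():
            raise ConfigError(f"parameter table missing: {self.parameters!r}")

    def window_plan(self) -> WindowPlan:
        return WindowPlan(
            window_length_ps=self.window_length_ps,
            n_windows_per_replicate=self.n_windows_per_replicate,
            n_replicates=len(self.trajectories),
            enthalpy_frames_per_window=self.enthalpy_frames_per_window,
        )


def _load_trajectory(path: str, dt: float) -> Trajectory:
    if str(path).endswith((".pdb", ".ent")):
        return load_trajectory_pdb(path, dt=dt)
    return load_trajectory_text(path)


def records_to_frame(records: list[DdGRecord]) -> pd.DataFrame:
    """Alanine-scan records as a table sorted by ΔΔG descending."""
    rows = []
    for r in records:
        rows.append({
            "mutation": r.label,
            "ddEvdw": f"{r.dd_e_vdw:.2f}±{r.sd_e_vdw:.2f}",
            "ddEele": f"{r.dd_e_ele:.2f}±{r.sd_e_ele:.2f}",
            "ddGgb": f"{r.dd_g_gb:.2f}±{r.sd_g_gb:.2f}",
            "ddGnp": f"{r.dd_g_np:.2f}±{r.sd_g_np:.2f}",
            "ddH": f"{r.dd_h:.2f}±{r.sd_h:.2f}",
            "-TddS": f"{r.minus_t_dd_s:.2f}±{r.sd_t_dd_s:.2f}",
            "ddG": f"{r.dd_g:.2f}±{r.sd_g:.2f}",
            "ddG_mean": r.dd_g,
        })
    df = pd.DataFrame(rows).sort_values("ddG_mean", ascending=False)
    return df.drop(columns="ddG_mean").reset_index(drop=True)


def _auto_hbond_candidates(system: ParamSystem) -> list[tuple[tuple[int, int], int]]:
    """Protein donor (heavy, H) pairs × ligand N/O/F acceptors, plus the
    reverse direction, from the inferred bond list."""
    h_parents = {}
    for i, j in system.bonds:
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.is_hydrogen and not aj.is_hydrogen:
            h_parents[i] = j
        elif aj.is_hydrogen and not ai.is_hydrogen:
            h_parents[j] = i
    lig = set(system.ligand_atom_indices.tolist())
    acceptors_elem = {"N", "O", "F"}
    pairs = []
    for h, heavy in h_parents.items():
        donor_in_lig = heavy in lig
        for k, atom in enumerate(system.atoms):
            if atom.is_hydrogen or atom.element.upper() not in acceptors_elem:
                continue
            if (k in lig) == donor_in_lig:
                continue
            pairs.append(((heavy, h), k))
    return pairs


def run_scan(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results (records, summaries, paths).
    Every table in the bundle is recomputable from the stored intermediate
    series; the JSON log records config, versions and timings per stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name):
        t0 = time.time()

        def done(**extra):
            log.append({"stage": name, "wall_s": round(time.time() - t0, 3),
                        **extra})
        return done

    try:
        done = stage("load")
        system = read_structure(config.structure,
                                ligand_resname=config.ligand_resname)
        if config.parameters:
            system = attach_parameters(system,
                                       read_parameter_table(config.parameters))
        system.classify_residues()
        replicates = [_load_trajectory(t, config.frame_interval_ps)
                      for t in config.trajectories]
        for tr in replicates:
            tr.check_against(system)
        done(n_atoms=system.n_atoms,
             n_frames=[t.n_frames for t in replicates])

        done = stage("stability")
        lig_heavy = [i for i in system.ligand_atom_indices
                     if not system.atoms[i].is_hydrogen]
        backbone = [i for i, a in enumerate(system.atoms)
                    if a.name in ("N", "CA", "C", "O")
                    and not system.residues[a.residue_index].is_ligand]
        ref = system.reference_coords
        lig_rmsd = [rmsd_series(t, ref, selection=lig_heavy) for t in replicates]
        bb_sel = backbone if len(backbone) >= 3 else None
        bb_rmsd = [rmsd_series(t, ref, selection=bb_sel) for t in replicates]
        for k, (lr, br) in enumerate(zip(lig_rmsd, bb_rmsd)):
            pd.DataFrame({"time_ps": replicates[k].times,
                          "backbone_rmsd_A": br,
                          "ligand_rmsd_A": lr}).to_csv(
                out / f"rmsd_rep{k + 1}.csv", index=False)
        bfac = bfactor(replicates[0])
        pd.DataFrame({"atom": [a.name for a in system.atoms],
                      "residue": [system.residues[a.residue_index].label
                                  for a in system.atoms],
                      "bfactor_A2": bfac}).to_csv(out / "bfactor.csv",
                                                  index=False)
        stride = max(1, replicates[0].n_frames // 50)
        m2d = rmsd_matrix(replicates[0], replicates[0], stride=stride)
        np.savetxt(out / "rmsd2d.csv", m2d, fmt="%.4f", delimiter=",")
        done()

        done = stage("windows")
        plan = config.window_plan()
        lengths = [t.n_frames * config.frame_interval_ps for t in replicates]
        windows = plan_windows(lengths, plan, stability_series=lig_rmsd,
                               frame_interval_ps=config.frame_interval_ps)
        done(n_windows=len(windows))

        # concatenate replicates into one trajectory with frame offsets
        offsets, acc = {}, 0
        for k, t in enumerate(replicates):
            offsets[k] = acc
            acc += t.n_frames
        coords = np.concatenate([t.coords for t in replicates])
        traj = Trajectory.from_coords(coords, dt=config.frame_interval_ps)

        done = stage("pocket")
        pocket = select_pocket(system, cutoff=config.pocket_cutoff)
        done(pocket=[system.residues[i].label for i in pocket])

        done = stage("scan")
        records = []
        for ridx in pocket:
            records.append(scan_residue(
                system, traj, windows, ridx, plan, T=config.temperature,
                k_sd=config.outlier_k_sd, sasa_points=config.sasa_points,
                frame_offsets=offsets))
        done(n_residues=len(records))

        done = stage("report")
        table = records_to_frame(records)
        table.to_csv(out / "alanine_scan.csv", index=False)
        hot = classify_hotspots(records, config.hotspot_threshold)
        (out / "hotspots.txt").write_text("\n".join(hot) + "\n")
        res_sum = residue_sum_summary(records)
        whole = binding_summary(system, traj, windows, plan,
                                T=config.temperature,
                                k_sd=config.outlier_k_sd,
                                sasa_points=config.sasa_points,
                                frame_offsets=offsets)
        summary = pd.DataFrame([
            {"route": "residue_sum", "dH": res_sum.dh_mean,
             "dH_sd": res_sum.dh_sd, "-TdS": res_sum.minus_tds_mean,
             "-TdS_sd": res_sum.minus_tds_sd, "dG": res_sum.dg_mean,
             "dG_sd": res_sum.dg_sd, "n_windows": res_sum.n_windows},
            {"route": "whole_complex", "dH": whole.dh_mean,
             "dH_sd": whole.dh_sd, "-TdS": whole.minus_tds_mean,
             "-TdS_sd": whole.minus_tds_sd, "dG": whole.dg_mean,
             "dG_sd": whole.dg_sd, "n_windows": whole.n_windows},
        ])
        summary.to_csv(out / "summary.csv", index=False)

        hb_rows = []
        for donor, acceptor in _auto_hbond_candidates(system):
            rec = hbond_occupancy(traj, donor, acceptor)
            if rec.occupancy >= 5.0:
                hb_rows.append({
                    "donor": system.atoms[donor[0]].name,
                    "hydrogen": system.atoms[donor[1]].name,
                    "acceptor": system.atoms[acceptor].name,
                    "mean_distance_A": round(rec.mean_distance, 2),
                    "mean_angle_deg": round(rec.mean_angle, 2),
                    "occupancy_pct": round(rec.occupancy, 2)})
        pd.DataFrame(hb_rows, columns=["donor", "hydrogen", "acceptor",
                                       "mean_distance_A", "mean_angle_deg",
                                       "occupancy_pct"]).to_csv(
            out / "hbonds.csv", index=False)
        done()
    except Exception as exc:
        log.append({"stage": "error", "error": str(exc),
                    "type": type(exc).__name__})
        (out / "run_log.json").write_text(
            "\n".join(json.dumps(e) for e in log) + "\n")
        raise

    run_log = {
        "version": __version__,
        "config": {k: getattr(config, k)
                   for k in config.__dataclass_fields__},
        "stages": log,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return {
        "records": records, "hotspots": hot, "summary_residue_sum": res_sum,
        "summary_whole_complex": whole,
        "total_binding": total_binding_energy(records),
        "windows": windows, "output_dir": str(out),
    }


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   pairing: dict[str, str], n_a: int = 15, n_b: int = 15,
                   alpha: float = 0.01) -> pd.DataFrame:
    """Paired per-residue ΔΔG differences between two scan tables.

    Tables need columns ``mutation``, ``dd_g``, ``sd_g``; the pairing maps
    residue labels of table A to labels of table B (e.g. Y889 → Y455).
    Differences are A − B with SDs propagated in quadrature and a Welch
    two-sample t-test on the window-level summary statistics; ``significant``
    flags p < ``alpha``. Unpaired residues are dropped.
    """
    def by_residue(tab):
        out = {}
        for _, row in tab.iterrows():
            label = str(row["mutation"])
            label = label[:-1] if label.endswith("A") else label
            out[label] = (float(row["dd_g"]), float(row["sd_g"]))
        return out

    a_map, b_map = by_residue(table_a), by_residue(table_b)
    rows = []
    for la, lb in pairing.items():
        if la not in a_map or lb not in b_map:
            continue
        (ma, sa), (mb, sb) = a_map[la], b_map[lb]
        diff = ma - mb
        sd = float(np.sqrt(sa**2 + sb**2))
        if sa == 0.0 and sb == 0.0:
            p = 0.0 if diff != 0 else 1.0
        else:
            _, p = stats.ttest_ind_from_stats(ma, sa, n_a, mb, sb, n_b,
                                              equal_var=False)
        rows.append({"residue_a": la, "residue_b": lb, "ddG_a": ma,
                     "ddG_b": mb, "difference": diff, "sd": sd,
                     "p_value": float(p), "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def compare_runs(bundle_a, bundle_b, pairing: dict[str, str],
                 alpha: float = 0.01) -> pd.DataFrame:
    """Compare two in-memory scan results (as returned by :func:`run_scan`)."""
    def to_table(bundle):
        return pd.DataFrame([{"mutation": r.label, "dd_g": r.dd_g,
                              "sd_g": r.sd_g} for r in bundle["records"]])

    n_a = bundle_a["records"][0].n_windows if bundle_a["records"] else 2
    n_b = bundle_b["records"][0].n_windows if bundle_b["records"] else 2
    return compare_tables(to_table(bundle_a), to_table(bundle_b), pairing,
                          n_a=n_a, n_b=n_b, alpha=alpha)
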