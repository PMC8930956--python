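"""Full-study orchestration: cohort x five constructs -> wear, stats, exports.

``run_study`` reproduces the complete comparison at desk scale: generate the
synthetic cohort, synthesize and average each patient's walking cycles,
simulate one wear cycle per construct, extrapolate to 1.0 million cycles,
and reduce to a Table-1-shaped report — per-construct wear summaries, paired
comparisons against the DM22PE control, and the JRF/BMI regressions.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so identical config + seed gives
bitwise-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    GaitParams,
    Patient,
    cohort_to_frame,
    representative_cycle,
    sample_cohort,
)
from .config import load_default_config, merge_config
from .implants import CONFIG_IDS, make_implant_spec
from .stats import ComparisonResult, RegressionResult, paired_comparison, regress_r2
from .wear import (
    SimulationParams,
    WearField,
    extrapolate_wear,
    simulate_cycle,
    summarize_wear,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "export_tables", "export_wear_map"]

log = logging.getLogger("dmwear")

CONTROL_ID = "DM22PE"


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to rerun a study: parameters, seeds, scope."""

    raw: dict
    seed: int = 0
    configs: tuple[str, ...] = CONFIG_IDS
    n_patients: int | None = None  # None -> cohort section value
    keep_fields: bool = False  # retain per-node wear fields in the result

    @staticmethod
    def from_dict(d: dict | None = None, **kwargs) -> "StudyConfig":
        raw = merge_config(load_default_config(), d or {})
        return StudyConfig(raw=raw, **kwargs)

    @property
    def gait_params(self) -> GaitParams:
        return GaitParams.from_dict(self.raw["gait"])

    @property
    def sim_params(self) -> SimulationParams:
        sim = self.raw["simulation"]
        return SimulationParams(
            mesh_edge_mm=float(sim["mesh_edge_mm"]),
            theta_lim_deg=float(sim["theta_lim_deg"]),
            mu=float(sim["mu"]),
            pressure_cap=bool(sim["pressure_cap"]),
            liner_init=str(sim["liner_init"]),
        )

    @property
    def n_cycles(self) -> float:
        return float(self.raw["simulation"]["n_cycles"])

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    config: StudyConfig
    cohort: list[Patient]
    wear_summaries: pd.DataFrame  # one row per patient x construct
    comparisons: pd.DataFrame  # vs DM22PE, volumetric + linear
    regressions: pd.DataFrame
    wear_fields: dict[tuple[str, str], list[WearField]] = field(default_factory=dict)
    peak_jrf: dict[str, float] = field(default_factory=dict)

    @property
    def metadata(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "configs": list(self.config.configs),
            "n_patients": len(self.cohort),
            "n_cycles": self.config.n_cycles,
            "control": CONTROL_ID,
        }


def _comparison_row(c: ComparisonResult, outcome: str) -> dict:
    return {
        "outcome": outcome,
        "config_id": c.label_b,
        "control": c.label_a,
        "n": c.n,
        "mean": c.mean_b,
        "sd": c.sd_b,
        "control_mean": c.mean_a,
        "control_sd": c.sd_a,
        "mean_diff": c.mean_diff,
        "sd_diff": c.sd_diff,
        "diff_ci_low": c.diff_ci[0],
        "diff_ci_high": c.diff_ci[1],
        "cohens_d": c.cohens_d,
        "d_ci_low": c.d_ci[0],
        "d_ci_high": c.d_ci[1],
        "p_value": c.p_value,
    }


def run_study(config: StudyConfig) -> StudyResult:
    """Run the study defined by ``config`` and assemble all result tables."""
    unknown = [c for c in config.configs if c not in CONFIG_IDS]
    if unknown:
        raise ValueError(f"unknown construct id(s): {unknown}")

    cohort_cfg = config.raw["cohort"]
    n = config.n_patients or int(cohort_cfg["n_patients"])
    n_male = min(int(cohort_cfg["n_male"]), n)
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, gait_seed_root = [int(s) for s in ss.generate_state(2) >> 1]

    cohort = sample_cohort(
        n=n,
        n_male=n_male,
        age_mean=float(cohort_cfg["age_mean"]),
        age_sd=float(cohort_cfg["age_sd"]),
        bmi_mean=float(cohort_cfg["bmi_mean"]),
        bmi_sd=float(cohort_cfg["bmi_sd"]),
        age_bounds=tuple(cohort_cfg["age_bounds"]),
        bmi_bounds=tuple(cohort_cfg["bmi_bounds"]),
        height_male=tuple(cohort_cfg["height_male"]),
        height_female=tuple(cohort_cfg["height_female"]),
        jrf_scale_sd=float(cohort_cfg["jrf_scale_sd"]),
        seed=cohort_seed,
    )

    gait_params = config.gait_params
    sim_params = config.sim_params
    sim_cfg = config.raw["simulation"]
    n_samples = int(sim_cfg["n_samples"])
    n_avg = int(sim_cfg.get("n_cycles_averaged", 11))
    overrides = config.raw.get("implants") or {}

    rows = []
    fields_store: dict[tuple[str, str], list[WearField]] = {}
    peak_jrf: dict[str, float] = {}
    for i, patient in enumerate(cohort):
        gait = representative_cycle(
            patient,
            gait_params,
            n_samples=n_samples,
            seed=(gait_seed_root + i) % (2**31),
            n_cycles=n_avg,
        )
        peak_jrf[patient.id] = gait.peak_jrf
        for config_id in config.configs:
            spec = make_implant_spec(config_id, **(overrides.get(config_id) or {}))
            fields = simulate_cycle(spec, gait, sim_params)
            fields = [extrapolate_wear(f, config.n_cycles) for f in fields]
            summary = summarize_wear(fields, patient.id, config_id)
            rows.append(
                {
                    "patient_id": patient.id,
                    "config_id": config_id,
                    "volumetric_wear_mm3": summary.volumetric_wear,
                    "linear_wear_mm": summary.linear_wear,
                    "volumetric_small_mm3": summary.volumetric_small,
                    "volumetric_large_mm3": summary.volumetric_large,
                    "cycles": summary.cycles,
                    "peak_jrf_N": gait.peak_jrf,
                    "bmi": patient.bmi,
                }
            )
            if config.keep_fields:
                fields_store[(patient.id, config_id)] = fields
        log.info(
            "patient %s done (%d/%d), peak JRF %.0f N",
            patient.id,
            i + 1,
            n,
            gait.peak_jrf,
        )
    wear_df = pd.DataFrame(rows)

    # paired comparisons vs the control, Table 1 layout
    comp_rows = []
    if CONTROL_ID in config.configs and n >= 2:
        d_method = str(config.raw["stats"].get("d_ci_method", "normal"))
        ctrl = wear_df[wear_df.config_id == CONTROL_ID].set_index("patient_id")
        for config_id in config.configs:
            if config_id == CONTROL_ID:
                continue
            other = wear_df[wear_df.config_id == config_id].set_index("patient_id")
            for outcome, col in (
                ("volumetric_wear_mm3", "volumetric_wear_mm3"),
                ("linear_wear_mm", "linear_wear_mm"),
            ):
                c = paired_comparison(
                    ctrl[col].to_numpy(),
                    other.loc[ctrl.index, col].to_numpy(),
                    label_a=CONTROL_ID,
                    label_b=config_id,
                    d_ci_method=d_method,
                )
                comp_rows.append(_comparison_row(c, outcome))
    comparisons = pd.DataFrame(comp_rows)

    # wear vs peak JRF and vs BMI for the dual-mobility constructs
    reg_rows = []
    if n >= 3:
        for config_id in config.configs:
            if not config_id.startswith("DM"):
                continue
            sub = wear_df[wear_df.config_id == config_id]
            for xname, xcol in (("peak_jrf_N", "peak_jrf_N"), ("bmi", "bmi")):
                r: RegressionResult = regress_r2(
                    sub[xcol].to_numpy(), sub["volumetric_wear_mm3"].to_numpy()
                )
                reg_rows.append(
                    {
                        "config_id": config_id,
                        "x": xname,
                        "y": "volumetric_wear_mm3",
                        "slope": r.slope,
                        "intercept": r.intercept,
                        "r_squared": r.r_squared,
                        "p_value": r.p_value,
                        "n": r.n,
                    }
                )
    regressions = pd.DataFrame(reg_rows)

    return StudyResult(
        config=config,
        cohort=cohort,
        wear_summaries=wear_df,
        comparisons=comparisons,
        regressions=regressions,
        wear_fields=fields_store,
        peak_jrf=peak_jrf,
    )


def export_wear_map(wear_field: WearField, path: str | Path, format: str = "vtk") -> Path:
    """Write a wear-depth map as VTK PolyData or PLY; returns the path."""
    from . import meshio

    path = Path(path)
    mesh = wear_field.mesh
    if format == "vtk":
        meshio.write_vtk_polydata(path, mesh.node_positions, mesh.triangles, wear_field.depth)
    elif format == "ply":
        meshio.write_ply(path, mesh.node_positions, mesh.triangles, wear_field.depth)
    else:
        raise ValueError("format must be 'vtk' or 'ply'")
    return path


def export_tables(result: StudyResult, out_dir: str | Path) -> dict[str, Path]:
    """Write wear_summaries.csv, comparisons.csv, regressions.csv, cohort.csv
    and metadata.json with stable ordering and float formatting."""
    missing = [
        name
        for name, df in (
            ("wear_summaries", result.wear_summaries),
            ("comparisons", result.comparisons),
            ("regressions", result.regressions),
        )
        if df is None or df.empty
    ]
    if missing:
        raise ValueError(f"incomplete study result; missing: {', '.join(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "wear_summaries": result.wear_summaries.sort_values(
            ["config_id", "patient_id"]
        ),
        "comparisons": result.comparisons,
        "regressions": result.regressions,
        "cohort": cohort_to_frame(result.cohort),
    }
    for name, df in frames.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.9g")
        paths[name] = p
    meta = out_dir / "metadata.json"
    meta.write_text(json.dumps(result.metadata, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = meta
    return paths
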