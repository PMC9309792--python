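"""End-to-end pipeline: volumes -> geometry -> masses -> model -> loads.

Mirrors a clinical workflow: take (or synthesize) labeled volumes, extract
geometry and alignment, partition tissue masses, assemble the static
model, find the upright-standing compensation posture, then run a battery
of static load cases through the muscle-force optimization and write
results.  Every output embeds the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy, geometry, mass_model, muscle_opt, statics, synthetic_spine
from .anatomy import SpineModel, load_param_json
from .statics import LoadCase
from .volume import LabeledVolume

__all__ = ["PipelineConfig", "PipelineError", "default_load_cases", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


#: Static loading tasks analogous to the published validation battery:
#: upright standing, standing with a 20 kg weight held at two anterior
#: offsets, arm elevation, and 10-30 degree flexion with and without 10 kg.
def default_load_cases() -> list[LoadCase]:
    cases = [
        LoadCase("standing"),
        LoadCase("standing_20kg_20cm", hand_mass_kg=20.0, load_offset_mm=200.0, reference="chest"),
        LoadCase("standing_20kg_55cm", hand_mass_kg=20.0, load_offset_mm=550.0, reference="chest"),
        LoadCase("elevate_both_arms", arms_elevated=True),
    ]
    for flex in (10.0, 20.0, 30.0):
        cases.append(LoadCase(f"flexion_{int(flex)}", trunk_flexion_deg=flex))
        cases.append(
            LoadCase(f"flexion_{int(flex)}_10kg", trunk_flexion_deg=flex, hand_mass_kg=10.0,
                     load_offset_mm=250.0, reference="chest")
        )
    return cases


@dataclass
class PipelineConfig:
    """Everything one run needs; file inputs or a synthetic preset."""

    out_dir: Path
    instance_path: Path | None = None
    subregion_path: Path | None = None
    intensity_path: Path | None = None
    synth_preset: str | None = "lordotic"  # straight | lordotic | scoliotic
    seed: int = 0
    stature_m: float = 1.75
    sigma_max_mpa: float = 1.0
    tol_nm: float = 0.1
    ligament_params: Path | None = None
    disc_params: Path | None = None
    muscle_table: Path | None = None
    load_cases: list[LoadCase] = field(default_factory=default_load_cases)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "preset": self.synth_preset,
                "seed": self.seed,
                "stature": self.stature_m,
                "sigma": self.sigma_max_mpa,
                "tol": self.tol_nm,
                "cases": [c.name for c in self.load_cases],
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_PRESETS = {
    "straight": dict(),
    "lordotic": dict(lumbar_lordosis_deg=29.0, thoracic_kyphosis_deg=31.0),
    "scoliotic": dict(lumbar_lordosis_deg=29.0, thoracic_kyphosis_deg=31.0, cobb_deg=18.0),
}


def synth_params(preset: str, seed: int = 0) -> synthetic_spine.SpineParams:
    if preset not in _PRESETS:
        raise PipelineError("synth", f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    return synthetic_spine.SpineParams(seed=seed, **_PRESETS[preset])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns a summary dict (alignment, masses, per-case joint loads,
    normalized compressions, ligament utilizations).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.time()
    meta = {"seed": config.seed, "config_hash": config.digest()}

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.time() - t_start:7.2f}s] {stage}: {msg}")

    # ------------------------------------------------------------------ volumes
    stage = "synth"
    try:
        if config.instance_path is not None:
            stage = "load"
            inst = LabeledVolume.load(config.instance_path)
            sub = LabeledVolume.load(config.subregion_path)
            tis = LabeledVolume.load(config.intensity_path) if config.intensity_path else None
            params = None
        else:
            params = synth_params(config.synth_preset or "lordotic", config.seed)
            inst, sub = synthetic_spine.generate_spine_volume(params)
            tis = synthetic_spine.generate_tissue_volume(params, inst)
        log(stage, f"volumes ready, grid {inst.voxels.shape}")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ----------------------------------------------------------------- geometry
    try:
        geoms, transform = geometry.extract_all(inst, sub)
        alignment = geometry.measure_alignment(geoms)
        log("extract", f"{len(geoms)} vertebrae; lordosis {alignment.lumbar_lordosis_deg:.1f} deg")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("extract", str(e)) from e

    # --------------------------------------------------------------------- mass
    try:
        densities = mass_model.DensityTable(**{
            k: v for k, v in load_param_json("densities").items() if not k.startswith("_")
        })
        if tis is None:
            raise ValueError("no intensity volume available for tissue classification")
        tissue = mass_model.classify_tissues(tis, bone_mask=inst.voxels > 0)
        segments = mass_model.assign_to_levels(tissue, geoms, densities, transform=transform)
        bones = {lev: mass_model.bone_mass(inst, lev, densities.bone) for lev in geoms}
        torso_mass = sum(s.mass_kg for s in segments) + sum(bones.values())
        anthro = load_param_json("anthropometry")
        generic = mass_model.scale_generic_segments(config.stature_m, torso_mass, anthro)
        log("mass", f"torso {torso_mass:.2f} kg, body {generic['body_mass_kg']:.2f} kg")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mass", str(e)) from e

    # -------------------------------------------------------------------- build
    try:
        model = anatomy.assemble_model(
            geoms,
            segments,
            generic,
            bones,
            ligament_params=load_param_json(config.ligament_params) if config.ligament_params else None,
            disc_params=load_param_json(config.disc_params) if config.disc_params else None,
            muscle_table=json.loads(Path(config.muscle_table).read_text()) if config.muscle_table else None,
            provenance=meta,
        )
        log("build", f"{len(model.muscles)} actuators, {len(model.ligaments)} ligaments, "
                     f"total mass {model.total_mass_kg:.2f} kg")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("build", str(e)) from e

    # ------------------------------------------------------------ neutral stance
    try:
        neutral = statics.neutral_posture(model)
        log("neutral", f"objective {getattr(neutral, 'objective', float('nan')):.3g}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("neutral", str(e)) from e

    # ---------------------------------------------------------------- load cases
    case_results: dict[str, dict] = {}
    reactions: dict[str, dict[str, dict[str, float]]] = {}
    force_rows = []
    for case in config.load_cases:
        try:
            posture = statics.compose_postures(
                neutral, statics.flexion_posture(model, case.trunk_flexion_deg)
            )
            problem = muscle_opt.build_problem(model, posture, case, config.sigma_max_mpa)
            sol = muscle_opt.solve(problem, tol_nm=config.tol_nm, seed=config.seed)
            reac = muscle_opt.joint_reactions(model, posture, sol.forces_n, case)
            util = muscle_opt.ligament_utilization(model, posture)
            reactions[case.name] = reac
            case_results[case.name] = {
                "reactions": reac,
                "ligament_utilization": util,
                "max_residual_nm": float(np.abs(sol.residuals_nm).max()),
                "cost": sol.cost,
            }
            for lbl, f in zip(sol.labels, sol.forces_n):
                force_rows.append({"case": case.name, "fascicle": lbl, "force_n": float(f)})
            log("simulate", f"{case.name}: L4/L5 compression "
                            f"{reac['L4/L5']['compression_n']:.0f} N")
        except muscle_opt.InfeasibleProblemError as e:
            raise PipelineError("simulate", f"{case.name}: {e}") from e
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", f"{case.name}: {e}") from e
    normalized = muscle_opt.normalize_to_standing(reactions) if "standing" in reactions else {}

    # ------------------------------------------------------------------ outputs
    summary = {
        **meta,
        "alignment": alignment.to_dict(),
        "torso_mass_kg": torso_mass,
        "body_mass_kg": generic["body_mass_kg"],
        "model_mass_kg": model.total_mass_kg,
        "n_muscles": len(model.muscles),
        "n_groups": len({m.group for m in model.muscles}),
        "neutral_angles_deg": {k: v.tolist() for k, v in neutral.joint_rotations_deg.items()},
        "cases": case_results,
        "normalized_compression": normalized,
    }
    model.save(out / "model.json")
    (out / "alignment.json").write_text(json.dumps({**meta, **alignment.to_dict()}, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame([{**meta, **s.to_dict(), "com_mm": None,
                   **{f"com_{ax}_mm": c for ax, c in zip("xyz", s.com_mm)}}
                  for s in segments]).drop(columns=["com_mm"]).to_csv(out / "segments.csv", index=False)
    rows = []
    for cname, joints in reactions.items():
        for jname, comps in joints.items():
            rows.append({"case": cname, "joint": jname, **comps,
                         "normalized_compression": normalized.get(cname, {}).get(jname)})
    pd.DataFrame(rows).to_csv(out / "joint_loads.csv", index=False)
    pd.DataFrame(force_rows).to_csv(out / "muscle_forces.csv", index=False)
    log("done", f"bundle written to {out}")
    (out / "run.log").write_text(
        "\n".join([f"seed={config.seed} config_hash={meta['config_hash']}"] + log_lines) + "\n"
    )
    return summary
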