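"""End-to-end pipeline stages: generate -> gape -> solve -> sweep -> compare.

Chains the package modules the way the comparative study is structured:
each model is generated, opened to its maximum gape, loaded by jaw adductors
(dry-skull force magnitudes) or head depressors, and solved; bite forces are
carried across body masses with 2/3-power allometry; muscle recruitments are
back-calculated by linearity; and stress summaries feed the comparison
tables.  Every stage is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sabrebite.config import RunConfig
from sabrebite.gape import GapeResult, find_max_gape, rotate_mandible
from sabrebite.musculature import build_adductor_fans, build_depressor_system
from sabrebite.scaling import (
    ModelRow,
    ScalingSpec,
    StressSummary,
    allometric_bite_force,
    back_calculate_recruitment,
    build_comparison_report,
    gape_sweep,
)
from sabrebite.simulate import BiteSimulation
from sabrebite.synthetic import SkullModel, make_skull_pair

log = logging.getLogger("sabrebite")


@dataclass
class StageLog:
    stage: str
    wall_s: float
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def emit(self):
        dig = " ".join(f"{k}={v}" for k, v in self.digests.items())
        log.info("stage=%s wall=%.2fs %s", self.stage, self.wall_s, dig)


def _digest(path: Path) -> str:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:12]


class timed_stage:
    """Context manager logging one StageLog record per executed stage."""

    def __init__(self, name: str):
        self.name = name
        self.record = None

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.record = StageLog(self.name, time.perf_counter() - self._t0)
        if exc[0] is None:
            self.record.emit()
        return False


@dataclass
class ModelRun:
    """All per-model pipeline products."""

    name: str
    skull: SkullModel
    gape: GapeResult
    posed: SkullModel                  # jaw at maximum gape
    adductor_bite_n: float             # dry-skull adductor-driven bite force
    adductor_force_n: float            # total adductor muscle force
    depressor_bite_n: float            # head-depressor-driven bite force
    depressor_force_n: float           # pretension budget


def run_model(cfg: RunConfig, seed: int | None = None) -> ModelRun:
    """Generate one model and run its gape estimate and unit bite solves."""
    seed = cfg.seed if seed is None else seed
    params = cfg.skull_params(seed)
    materials = cfg.materials()
    g = cfg["gape"]
    mus = cfg["muscles"]

    with timed_stage(f"{cfg['name']}:generate"):
        skull = make_skull_pair(params)
    with timed_stage(f"{cfg['name']}:gape"):
        gape = find_max_gape(skull, cartilage_mm=g["cartilage_mm"],
                             backoff_deg=g["backoff_deg"],
                             contact_tol=g["contact_tol_mm"],
                             angle_res_deg=g["angle_resolution_deg"])
    posed = rotate_mandible(skull, gape.max_gape_deg - skull.rest_gape_deg)

    with timed_stage(f"{cfg['name']}:solve-adductor"):
        sim_a = BiteSimulation(posed, materials=materials)
        fans = build_adductor_fans(
            posed, n_trusses=mus["adductor_trusses_per_group"], seed=seed)
        sim_a.attach_muscles(fans)
        res_a = sim_a.solve()
        bite_a = sim_a.bite_force(res_a).magnitude

    with timed_stage(f"{cfg['name']}:solve-depressor"):
        sim_d = BiteSimulation(posed, materials=materials)
        dep = build_depressor_system(
            posed, ellipse_axes=tuple(mus["ellipse_axes_mm"]),
            circle_radius=mus["circle_radius_mm"],
            n_sterno=mus["n_sternomastoideus"],
            n_obliquus=mus["n_obliquus_capitis"],
            pretension=mus["pretension_n"],
            standoff_frac=mus["web_standoff_frac"], seed=seed)
        sim_d.attach_depressors(dep)
        res_d = sim_d.solve()
        bite_d = sim_d.bite_force(res_d).magnitude

    return ModelRun(name=cfg["name"], skull=skull, gape=gape, posed=posed,
                    adductor_bite_n=bite_a,
                    adductor_force_n=sim_a.total_muscle_force,
                    depressor_bite_n=bite_d,
                    depressor_force_n=dep.force_budget)


def scaled_model_row(cfg: RunConfig, run: ModelRun, target_bite_n: float,
                     seed: int | None = None, muscles: str = "adductor"
                     ) -> ModelRow:
    """Comparison-table row at the body-mass-scaled bite force.

    Rebuilds the model's muscle system, back-calculates the recruitment that
    delivers ``target_bite_n`` at the canines, re-solves at that recruitment
    and summarises the stresses.
    """
    seed = cfg.seed if seed is None else seed
    mus = cfg["muscles"]
    sim = BiteSimulation(run.posed, materials=cfg.materials())
    if muscles == "adductor":
        sim.attach_muscles(build_adductor_fans(
            run.posed, n_trusses=mus["adductor_trusses_per_group"],
            seed=seed))
    else:
        sim.attach_depressors(build_depressor_system(
            run.posed, ellipse_axes=tuple(mus["ellipse_axes_mm"]),
            circle_radius=mus["circle_radius_mm"],
            n_sterno=mus["n_sternomastoideus"],
            n_obliquus=mus["n_obliquus_capitis"],
            pretension=mus["pretension_n"],
            standoff_frac=mus["web_standoff_frac"], seed=seed))
    rec = back_calculate_recruitment(sim, target_bite_n)
    sim.scale_muscle_forces(rec.scale)
    res = sim.solve()
    summary = StressSummary.from_solve(sim, res)
    return ModelRow(name=run.name, body_mass=run.skull.body_mass,
                    muscle_recruitment=rec.muscle_force,
                    bite_force=target_bite_n,
                    region_means=summary.region_means,
                    landmark_mean=summary.landmark_mean)


def compare_profiles(configs: list, seed: int, reference: str | None = None,
                     muscles: str = "adductor"):
    """Full cross-model comparison.

    The reference model bites with its own (dry-skull or pretension-budget)
    muscle forces; every model's target bite force is the reference bite
    force carried to its body mass by the 2/3-power rule; rows report the
    recruitment and stress state at that target.

    Returns ``(ComparisonReport, list[ModelRun])``.
    """
    runs = [run_model(cfg, seed) for cfg in configs]
    names = [r.name for r in runs]
    if reference is None:
        reference = configs[0]["scaling"]["reference"]
        if reference not in names:
            reference = names[0]
    ref = runs[names.index(reference)]
    ref_bite = (ref.adductor_bite_n if muscles == "adductor"
                else ref.depressor_bite_n)
    exponent = float(configs[0]["scaling"]["exponent"])

    rows = []
    for cfg, run in zip(configs, runs):
        target = allometric_bite_force(ScalingSpec(
            reference_force=ref_bite, reference_mass=ref.skull.body_mass,
            target_mass=run.skull.body_mass, exponent=exponent))
        rows.append(scaled_model_row(cfg, run, target, seed, muscles))
    report = build_comparison_report(rows, reference=reference)
    return report, runs


def sweep_model(cfg: RunConfig, seed: int | None = None):
    """Bite force and recruitment across the configured gape angles."""
    seed = cfg.seed if seed is None else seed
    skull = make_skull_pair(cfg.skull_params(seed))
    angles = [float(a) for a in cfg["scaling"]["sweep_angles_deg"]]
    return gape_sweep(skull, angles, seed=seed,
                      n_trusses=cfg["muscles"]["adductor_trusses_per_group"])
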