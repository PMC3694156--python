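"""Allometric scaling, muscle-recruitment back-calculation, gape sweeps and
stress summary statistics for cross-model comparison.

Bite force is expected to scale with body mass to the 2/3 power (muscle force
is proportional to cross-sectional area, body mass to volume), so a reference
model's bite force is carried to other body masses as
F = F_ref * (M / M_ref)^(2/3).  Because the finite-element solves are linear,
the muscle force needed to reach a target bite force is a single solve:
scale = target / bite force at unit muscle recruitment.

Comparative outputs follow the layout of published comparative tables: per model the
body mass, muscle recruitment, canine bite force, and mean von Mises stress
by region (tooth root, canine crowns, zygomatic arch, rest of the cranium,
mandible) plus mean landmark-point stress; and a ratio block against a
designated reference model (the choice of reference is immaterial to the
ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sabrebite.fem import SolveResult
from sabrebite.mesh import TetMesh, find_enclosing_tet
from sabrebite.simulate import BiteSimulation
from sabrebite.synthetic import SkullModel


@dataclass(frozen=True)
class ScalingSpec:
    """Allometric bite-force transfer between body masses."""

    reference_force: float      # N
    reference_mass: float       # kg
    target_mass: float          # kg
    exponent: float = 2.0 / 3.0

    def __post_init__(self):
        if self.reference_mass <= 0 or self.target_mass <= 0:
            raise ValueError("masses must be positive")
        if not (0 < self.exponent <= 1):
            raise ValueError("exponent must lie in (0, 1]")


def allometric_bite_force(spec: ScalingSpec) -> float:
    """F_target = F_ref x (M_target / M_ref)^exponent (N)."""
    return spec.reference_force * (
        spec.target_mass / spec.reference_mass) ** spec.exponent


@dataclass
class RecruitmentResult:
    scale: float                # multiplier on the unit-case muscle forces
    muscle_force: float         # N, absolute recruitment = scale x unit total
    unit_bite_force: float      # N, bite reaction of the unit solve
    target_bite_force: float


def back_calculate_recruitment(sim: BiteSimulation,
                               target_bite_force: float,
                               result: SolveResult | None = None
                               ) -> RecruitmentResult:
    """Muscle recruitment needed for a target canine bite force.

    Exploits linearity: one solve at the attached (unit) muscle forces gives
    the bite reaction; the required recruitment is the proportional scaling
    of every muscle force.
    """
    if result is None:
        result = sim.solve()
    unit = sim.bite_force(result).magnitude
    if unit < 1e-9:
        raise RuntimeError("muscle system produces no bite reaction at the "
                           "canines; cannot back-calculate recruitment")
    scale = target_bite_force / unit
    return RecruitmentResult(scale=scale,
                             muscle_force=scale * sim.total_muscle_force,
                             unit_bite_force=unit,
                             target_bite_force=target_bite_force)


def recruitment_ratio(force_a: float, force_b: float) -> float:
    """Ratio a/b of two muscle recruitments (rendered at one decimal in
    reports)."""
    if force_b <= 0:
        raise ValueError("reference force must be positive")
    return force_a / force_b


# ---------------------------------------------------------------------------
# gape sweep
# ---------------------------------------------------------------------------

def gape_sweep(skull: SkullModel, angles, target_bite_force: float | None = None,
               seed: int = 0, muscle_spec=None, n_trusses: int = 10
               ) -> pd.DataFrame:
    """Adductor-driven bite force and recruitment across jaw opening angles.

    For each angle the mandible is rotated about the hinge, the adductor fans
    are rebuilt at that pose (muscle tension itself does not change with
    gape), the model is solved, and the canine bite reaction recorded.  The
    recruitment column is the muscle force needed to reach
    ``target_bite_force`` (default: the bite force at the first angle), which
    by linearity is target / bite force pointwise.  Infeasible angles are
    flagged and skipped rather than aborting the sweep.
    """
    from sabrebite.gape import rotate_mandible
    from sabrebite.musculature import build_adductor_fans

    rows = []
    target = target_bite_force
    for ang in angles:
        try:
            posed = rotate_mandible(skull, float(ang))
            sim = BiteSimulation(posed)
            fans = build_adductor_fans(posed, spec=muscle_spec,
                                       n_trusses=n_trusses, seed=seed)
            sim.attach_muscles(fans)
            res = sim.solve()
            bf = sim.bite_force(res).magnitude
            muscle = sim.total_muscle_force
            if target is None:
                target = bf
            rows.append(dict(angle_deg=float(ang), feasible=True,
                             bite_force_n=bf, muscle_force_n=muscle,
                             recruitment_n=target / bf * muscle,
                             recruitment_scale=target / bf))
        except Exception as exc:       # infeasible pose: flag, continue
            rows.append(dict(angle_deg=float(ang), feasible=False,
                             bite_force_n=np.nan, muscle_force_n=np.nan,
                             recruitment_n=np.nan, recruitment_scale=np.nan))
            warnings.warn(f"gape sweep angle {ang} infeasible: {exc}",
                          RuntimeWarning, stacklevel=2)
    df = pd.DataFrame(rows)
    df.attrs["target_bite_force_n"] = target
    return df


# ---------------------------------------------------------------------------
# stress summaries
# ---------------------------------------------------------------------------

def mean_region_vm(result: SolveResult, element_idx, mesh: TetMesh | None = None,
                   volume_weighted: bool = False) -> float:
    """Mean element ("brick") von Mises stress over a region (MPa).

    Arithmetic mean by default, matching mean-brick-stress protocols; pass
    ``volume_weighted=True`` (with the mesh) for the volume-weighted variant.
    """
    idx = np.asarray(element_idx, dtype=int)
    if idx.size == 0:
        raise ValueError("region is empty")
    vm = result.vm[idx]
    if volume_weighted:
        if mesh is None:
            raise ValueError("volume weighting needs the mesh")
        w = mesh.tet_volumes()[idx]
        return float((vm * w).sum() / w.sum())
    return float(vm.mean())


def mean_landmark_vm(result: SolveResult, mesh: TetMesh, landmarks: dict,
                     max_outside: float = 1.0):
    """Von Mises stress at homologous landmark points.

    Each landmark reports the stress of its enclosing element (nearest
    element if up to ``max_outside`` mm outside the surface); landmarks
    farther outside are excluded from the mean with a warning.  Returns
    ``(per-landmark dict, mean, missing names)``.
    """
    per = {}
    missing = []
    for name, pt in landmarks.items():
        ti = find_enclosing_tet(mesh, pt, max_outside=max_outside)
        if ti is None:
            missing.append(name)
            continue
        per[name] = float(result.vm[ti])
    if missing:
        warnings.warn(f"landmarks outside the mesh excluded from the mean: "
                      f"{missing}", RuntimeWarning, stacklevel=2)
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean, missing


@dataclass
class StressSummary:
    """Mean brick VM per region plus landmark-point stresses (MPa)."""

    region_means: dict
    landmark_vm: dict
    landmark_mean: float

    @classmethod
    def from_solve(cls, sim: BiteSimulation, result: SolveResult,
                   volume_weighted: bool = False) -> "StressSummary":
        regions = sim.region_partition()
        means = {name: mean_region_vm(result, idx, sim.mesh, volume_weighted)
                 for name, idx in regions.items() if len(idx)}
        lms = {n: sim.skull.landmarks[n] for n in sim.skull.stress_landmarks}
        # landmark lookup on the merged mesh (cranium + mandible)
        per, mean, _ = mean_landmark_vm(result, sim.mesh, lms)
        return cls(region_means=means, landmark_vm=per, landmark_mean=mean)


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

REGION_COLUMNS = ("tooth_root", "canine_crowns", "zygomatic_arch",
                  "rest_of_cranium", "mandible")


@dataclass
class ModelRow:
    """One model's entry in the comparison report (forces in N, stress MPa)."""

    name: str
    body_mass: float
    muscle_recruitment: float
    bite_force: float
    region_means: dict = field(default_factory=dict)
    landmark_mean: float = float("nan")


@dataclass
class ComparisonReport:
    """Comparative table plus ratio block against a reference model.

    ``table`` mirrors the published comparative layout (mass, recruitment, bite force,
    region stress means); ``ratios`` holds each model's recruitment and
    region-stress ratios against the reference, rendered at one decimal.
    Forces are rounded to whole newtons and stresses to three decimals in
    ``rounded_table``; full precision is retained in ``table``.
    """

    table: pd.DataFrame
    ratios: pd.DataFrame
    reference: str

    @property
    def rounded_table(self) -> pd.DataFrame:
        out = self.table.copy()
        for c in ("muscle_recruitment_n", "bite_force_n"):
            out[c] = out[c].round(0).astype("Int64")
        for c in out.columns:
            if c.endswith("_mpa"):
                out[c] = out[c].round(3)
        return out

    def to_csv(self, table_path, ratios_path=None) -> None:
        self.table.to_csv(table_path, index=False)
        if ratios_path is not None:
            self.ratios.to_csv(ratios_path, index=False)

    @classmethod
    def from_csv(cls, table_path, ratios_path, reference: str):
        return cls(pd.read_csv(table_path), pd.read_csv(ratios_path),
                   reference)


def build_comparison_report(rows, reference: str | None = None
                            ) -> ComparisonReport:
    """Assemble the cross-model comparison from per-model entries.

    ``rows`` are ModelRow records (computed by the pipeline, or injected from
    published numbers for checking).  Ratios are taken against ``reference``
    (default: the first row); the reference's own ratios are exactly 1.0.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("need at least two models to compare")
    names = [r.name for r in rows]
    if reference is None:
        reference = names[0]
    if reference not in names:
        raise ValueError(f"reference '{reference}' not among {names}")
    region_sets = [tuple(sorted(r.region_means)) for r in rows]
    if len(set(region_sets)) > 1:
        raise ValueError("models carry inconsistent stress-region sets")

    recs = []
    for r in rows:
        rec = dict(model=r.name, body_mass_kg=r.body_mass,
                   muscle_recruitment_n=r.muscle_recruitment,
                   bite_force_n=r.bite_force,
                   landmark_mean_vm_mpa=r.landmark_mean)
        for k, v in r.region_means.items():
            rec[f"{k}_vm_mpa"] = v
        recs.append(rec)
    table = pd.DataFrame(recs)

    ref = next(r for r in rows if r.name == reference)
    ratio_recs = []
    for r in rows:
        rec = dict(model=r.name, reference=reference,
                   recruitment_ratio=round(
                       recruitment_ratio(r.muscle_recruitment,
                                         ref.muscle_recruitment), 1))
        for k in r.region_means:
            denom = ref.region_means[k]
            rec[f"{k}_stress_ratio"] = (round(r.region_means[k] / denom, 1)
                                        if denom > 0 else float("nan"))
        ratio_recs.append(rec)
    ratios = pd.DataFrame(ratio_recs)
    return ComparisonReport(table=table, ratios=ratios, reference=reference)
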