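"""Study orchestration: fracture-fixation matrix, healthy bite force, mesh
convergence.

The full study covers 4 fracture sites x 3 device materials x 2 plate
thicknesses = 24 scenarios under 20% post-operative unilateral-clenching
loads.  Each scenario reports healing-region dominant-strain box statistics,
the device peak von Mises stress with its yield ratio, and the occlusal
(bite-force) reaction.  `healthy` mode solves the intact mandible and reports
the bite force; `convergence` mode re-meshes the intact mandible at a series
of edge lengths with simplified isotropic bone properties (cortical 15000
MPa, trabecular 300 MPa, Poisson 0.3) under the simplified masseter load
(0, -50, +50) N and reports the relative change of symphysis-region average
von Mises stress and principal strains between refinement levels.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fem
from .geometry import (
    FRACTURE_SITES,
    FractureSpec,
    MandibleParams,
    build_mandible,
    insert_fracture,
)
from .fixation import place_devices
from .loading import build_load_case, convergence_load_case
from .materials import (
    DEVICE_MATERIALS,
    MaterialCard,
    assign_materials,
    load_material_table,
)
from .postprocess import device_stress_summary, summarize_healing, von_mises

STUDY_COLUMNS = [
    "site", "material", "thickness", "n_elems", "n_nodes", "n_screws",
    "tens_min", "tens_q1", "tens_median", "tens_q3", "tens_max",
    "comp_min", "comp_q1", "comp_median", "comp_q3", "comp_max",
    "median_abs_strain_pct", "fraction_under_15pct",
    "peak_vm_MPa", "yield_strength_MPa", "yield_ratio", "elastic",
    "bite_force_N", "equilibrium_residual_N", "solver_residual",
    "min_scaled_jacobian", "runtime_s",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full run (study / healthy / convergence)."""

    geometry: MandibleParams = field(default_factory=MandibleParams)
    sites: tuple = FRACTURE_SITES
    materials: tuple = DEVICE_MATERIALS
    thicknesses: tuple = (1.0, 1.5)
    scale: float = 0.2
    mode: str = "study"
    convergence_edges: tuple = (1.0, 0.5)
    convergence_patch_radius: float = 2.5
    seed: int = 0
    outdir: str | None = None
    export_vtu: bool = False

    def __post_init__(self):
        if not (0.0 < self.scale <= 1.0):
            raise PipelineError("loading scale must lie in (0, 1]")
        if self.mode not in ("study", "healthy", "convergence"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        for s in self.sites:
            if s not in FRACTURE_SITES:
                raise PipelineError(f"unknown fracture site {s!r}")
        for m in self.materials:
            if m not in DEVICE_MATERIALS:
                raise PipelineError(f"unknown device material {m!r}")
        for t in self.thicknesses:
            if t not in (1.0, 1.5):
                raise PipelineError("plate thickness must be 1.0 or 1.5 mm")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        geo = MandibleParams(**raw.get("geometry", {}))
        study = raw.get("study", {})
        loading = raw.get("loading", {})
        conv = raw.get("convergence", {})
        out = raw.get("output", {})
        return cls(
            geometry=geo,
            sites=tuple(study.get("sites", FRACTURE_SITES)),
            materials=tuple(study.get("materials", DEVICE_MATERIALS)),
            thicknesses=tuple(raw.get("fixation", {}).get("thicknesses", (1.0, 1.5))),
            scale=loading.get("scale", 0.2),
            mode=raw.get("mode", "study"),
            convergence_edges=tuple(conv.get("edges", (1.0, 0.5))),
            convergence_patch_radius=conv.get("patch_radius", 2.5),
            seed=raw.get("seed", 0),
            outdir=out.get("directory"),
            export_vtu=out.get("export_vtu", False),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def solve_scenario(
    merged, C_global, yield_strength, scale=0.2, ties=None, K=None
):
    """Solve one fixed-fracture scenario and post-process it."""
    loads, bcs = build_load_case(merged, scale=scale)
    if ties is None:
        ties = fem.build_ties(merged)
    system = fem.assemble(merged, C_global, ties=ties, bcs=bcs, loads=loads, K=K)
    sol = fem.solve(system)
    healing = summarize_healing(sol)
    device = device_stress_summary(sol, yield_strength)
    reactions = fem.reaction_forces(sol)
    return sol, healing, device, reactions


def run_study(config: RunConfig, log=print) -> pd.DataFrame:
    """Run the scenario matrix; one report row per (site, material, thickness)."""
    cards = load_material_table()
    base = build_mandible(config.geometry)
    rows = []
    failures = []
    for site in config.sites:
        fractured = insert_fracture(base, FractureSpec(site))
        for thickness in config.thicknesses:
            fix, merged = place_devices(fractured, site, thickness)
            ties = fem.build_ties(merged)
            dev_ids = np.nonzero(np.isin(merged.region, ("plate", "screw")))[0]
            bone_ids = np.setdiff1d(np.arange(merged.n_elems), dev_ids)
            K_bone = None
            for material in config.materials:
                t0 = time.time()
                try:
                    _, C = assign_materials(merged, material, cards=cards)
                    if K_bone is None:
                        K_bone = fem.stiffness_csr(merged, C, bone_ids)
                    K = K_bone + fem.stiffness_csr(merged, C, dev_ids)
                    sol, healing, device, reactions = solve_scenario(
                        merged, C, cards[material].yield_strength,
                        scale=config.scale, ties=ties, K=K,
                    )
                except Exception as exc:  # continue remaining scenarios
                    failures.append((site, material, thickness, repr(exc)))
                    log(f"[FAIL] {site}/{material}/t{thickness}: {exc!r}")
                    continue
                row = {
                    "site": site, "material": material, "thickness": thickness,
                    "n_elems": merged.n_elems, "n_nodes": merged.n_nodes,
                    "n_screws": fix.n_screws,
                    "median_abs_strain_pct": healing.median_abs_pct,
                    "fraction_under_15pct": healing.fraction_under_15pct,
                    "peak_vm_MPa": device.peak,
                    "yield_strength_MPa": device.yield_strength,
                    "yield_ratio": device.yield_ratio,
                    "elastic": device.elastic,
                    "bite_force_N": -reactions["occlusal_right"][2],
                    "equilibrium_residual_N": reactions["_equilibrium_residual"],
                    "solver_residual": sol.residual,
                    "min_scaled_jacobian": merged.meta.get(
                        "min_scaled_jacobian", base.meta["min_scaled_jacobian"]
                    ),
                    "runtime_s": time.time() - t0,
                }
                for pre, stats in (("tens", healing.tensile), ("comp", healing.compressive)):
                    for k in ("min", "q1", "median", "q3", "max"):
                        row[f"{pre}_{k}"] = stats[k]
                rows.append(row)
                log(
                    f"{site}/{material}/t{thickness}: med|eps| "
                    f"{healing.median_abs_pct:.3f}% peak {device.peak:.1f} MPa "
                    f"(yield ratio {device.yield_ratio:.3f}) "
                    f"[{row['runtime_s']:.1f}s]"
                )
                if config.export_vtu and config.outdir:
                    _export_scenario(config, merged, sol, site, material, thickness)
    df = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    if config.outdir:
        _write_outputs(config, df, failures, "study")
    if failures and not rows:
        raise PipelineError(f"all scenarios failed: {failures}")
    return df


def run_healthy(config: RunConfig, log=print) -> dict:
    """Intact mandible under the clenching loads; bite-force readout."""
    mesh = build_mandible(config.geometry)
    _, C = assign_materials(mesh, "Ti-6Al-4V")
    loads, bcs = build_load_case(mesh, scale=config.scale)
    system = fem.assemble(mesh, C, bcs=bcs, loads=loads)
    sol = fem.solve(system)
    reactions = fem.reaction_forces(sol)
    out = {
        "bite_force_N": float(-reactions["occlusal_right"][2]),
        "condyle_right_N": reactions["condyle_right"].tolist(),
        "condyle_left_N": reactions["condyle_left"].tolist(),
        "equilibrium_residual_N": reactions["_equilibrium_residual"],
        "n_elems": mesh.n_elems,
        "scale": config.scale,
    }
    log(f"healthy mandible: bite force {out['bite_force_N']:.2f} N")
    if config.outdir:
        path = Path(config.outdir)
        path.mkdir(parents=True, exist_ok=True)
        (path / "healthy.json").write_text(json.dumps(out, indent=2))
    return out


def _iso_bone_cards() -> dict:
    """Simplified isotropic bone properties for the convergence runs."""
    iso = {}
    for name in (
        "symphysis", "body", "angle", "ramus", "condyle",
        "coronoid_process", "teeth",
    ):
        iso[name] = MaterialCard(name, 15000.0, 15000.0, 15000.0,
                                 0.3, 0.3, 0.3, isotropic=True)
    iso["trabecular"] = MaterialCard("trabecular", 300.0, 300.0, 300.0,
                                     0.3, 0.3, 0.3, isotropic=True)
    return iso


def convergence_level(params: MandibleParams, patch_radius: float = 2.5):
    """Solve one refinement level of the convergence study.

    Returns per-level metrics: volume-weighted symphysis-region average von
    Mises stress and average max/min principal strains.
    """
    mesh = build_mandible(params)
    _, C = assign_materials(mesh, "Ti-6Al-4V", override=_iso_bone_cards())
    loads, bcs = convergence_load_case(mesh, radius=patch_radius)
    system = fem.assemble(mesh, C, bcs=bcs, loads=loads)
    sol = fem.solve(system)

    sym = np.nonzero(mesh.region == "symphysis")[0]
    w = sol.point_weights[sym].ravel()
    vm = von_mises(sol.stress[sym].reshape(-1, 6))
    from .postprocess import principal_strains

    emax, emin = principal_strains(sol.strain[sym].reshape(-1, 6))
    reactions = fem.reaction_forces(sol)
    return {
        "edge_mm": params.target_edge_length,
        "n_elems": mesh.n_elems,
        "n_nodes": mesh.n_nodes,
        "avg_vm_MPa": float(np.average(vm, weights=w)),
        "avg_eps_max": float(np.average(emax, weights=w)),
        "avg_eps_min": float(np.average(emin, weights=w)),
        "equilibrium_residual_N": reactions["_equilibrium_residual"],
        "total_reaction_N": reactions["_total_reaction"].tolist(),
    }


def run_convergence(config: RunConfig, log=print) -> pd.DataFrame:
    """Refinement series; relative errors are taken against the finest level."""
    rows = []
    for h in sorted(config.convergence_edges, reverse=True):
        params = dataclasses.replace(config.geometry, target_edge_length=h)
        t0 = time.time()
        row = convergence_level(params, config.convergence_patch_radius)
        row["runtime_s"] = time.time() - t0
        rows.append(row)
        log(
            f"edge {h} mm: {row['n_elems']} elems, symphysis avg vM "
            f"{row['avg_vm_MPa']:.4f} MPa [{row['runtime_s']:.1f}s]"
        )
    df = pd.DataFrame(rows)
    ref = df.iloc[-1]
    for col in ("avg_vm_MPa", "avg_eps_max", "avg_eps_min"):
        df[f"relerr_{col}_pct"] = 100.0 * np.abs(df[col] - ref[col]) / np.abs(ref[col])
    if config.outdir:
        _write_outputs(config, df, [], "convergence")
    return df


def run(config: RunConfig, log=print):
    """Dispatch on config.mode; returns the mode's report object."""
    if config.mode == "study":
        return run_study(config, log=log)
    if config.mode == "healthy":
        return run_healthy(config, log=log)
    return run_convergence(config, log=log)


def _write_outputs(config: RunConfig, df: pd.DataFrame, failures, tag: str):
    path = Path(config.outdir)
    path.mkdir(parents=True, exist_ok=True)
    df.to_csv(path / f"{tag}_report.csv", index=False, float_format="%.9g")
    manifest = {
        "mode": tag,
        "seed": config.seed,
        "geometry": dataclasses.asdict(config.geometry),
        "scale": config.scale,
        "sites": list(config.sites),
        "materials": list(config.materials),
        "thicknesses": list(config.thicknesses),
        "failures": failures,
    }
    (path / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _export_scenario(config, mesh, sol, site, material, thickness):
    from .postprocess import dominant_strain, principal_strains
    from .vtu import write_vtu

    path = Path(config.outdir)
    path.mkdir(parents=True, exist_ok=True)
    vm = von_mises(sol.stress).mean(axis=1)
    emax, emin = principal_strains(sol.strain.mean(axis=1))
    dom = dominant_strain(emax, emin) * 100.0
    write_vtu(
        path / f"{site}_{material}_t{thickness}.vtu",
        mesh,
        point_data={"displacement": sol.u},
        cell_data={"von_mises_MPa": vm, "dominant_strain_pct": dom},
    )
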