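"""Single-run and batch execution of the simulation pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import activation as act_mod
from .config import RunSpec, save_spec
from .geometry import generate_hex_mesh
from .postprocess import report_run
from .solver import ThreeFieldState, run_quasistatic
from .vtu import write_vtu

__all__ = ["RunResult", "run_single", "run_matrix", "PATTERN_VARIANT_GRID"]

PATTERN_VARIANT_GRID = [
    (p, v)
    for v in ("compliant", "normal", "stiff")
    for p in ("uniform", "proximal_distal", "midline", "medial_lateral")
]


@dataclass
class RunResult:
    spec: RunSpec
    mesh: object
    activation: object
    states: List[ThreeFieldState]
    log: list
    summary: dict


def run_single(spec: RunSpec, write_outputs: Optional[bool] = None
               ) -> RunResult:
    """Execute geometry -> mesh -> calibrate -> solve -> postprocess.

    If the spec names an output directory (or ``write_outputs`` is True),
    the bundle (per-step VTU, summary CSV row, convergence log and the
    exact spec used) is written there.
    """
    mesh = generate_hex_mesh(spec.geometry, spec.resolution)
    field = spec.activation
    if field.pattern != "uniform" and not field.calibrated:
        field = act_mod.calibrate_region(field, mesh)
    states, log = run_quasistatic(mesh, spec.material, field, spec.solver)
    meta = {
        "mean_activation_end": act_mod.mean_activation(
            mesh, field, field.ramp_duration),
        "transition_width_mm": field.transition_width,
        "region_boundary_mm": field.boundary,
        "active_side": field.active_side,
        "n_load_steps": spec.solver.n_load_steps,
        "resolution": f"{spec.resolution.nx}x{spec.resolution.ny_apo}+"
                      f"{spec.resolution.ny_muscle}+{spec.resolution.ny_apo}"
                      f"x{spec.resolution.nz}",
    }
    summary = report_run(states, mesh, spec.material, field, metadata=meta)
    result = RunResult(spec=spec, mesh=mesh, activation=field,
                       states=states, log=log, summary=summary)
    if write_outputs or (write_outputs is None and spec.output_dir):
        _write_bundle(result)
    return result


def _write_bundle(result: RunResult) -> None:
    out = Path(result.spec.output_dir or "pennatefem_out")
    out.mkdir(parents=True, exist_ok=True)
    save_spec(result.spec, out / "spec.yaml")
    pd.DataFrame(result.log).to_csv(out / "convergence.csv", index=False)
    pd.DataFrame([result.summary]).to_csv(out / "summary.csv", index=False)
    mesh = result.mesh
    for st in result.states:
        cell_alpha = st.alpha_qp.mean(axis=1)
        write_vtu(
            out / f"state_{st.load_step:03d}.vtu", mesh,
            point_data={"u": st.u},
            cell_data={"region": mesh.cell_region.astype(float),
                       "p_tilde": st.p_tilde, "J_tilde": st.J_tilde,
                       "alpha": cell_alpha,
                       "fiber_a0": mesh.fiber_a0})


def run_matrix(resolution=None, solver=None, output_dir=None,
               variants=("compliant", "normal", "stiff"),
               patterns=("uniform", "proximal_distal", "midline",
                         "medial_lateral")) -> pd.DataFrame:
    """Run the full activation-pattern x aponeurosis-stiffness grid.

    Individual failures are recorded in the summary (column ``error``)
    without aborting the batch.  Returns one row per condition.
    """
    from .geometry import Resolution
    from .solver import SolverConfig
    resolution = resolution or Resolution()
    solver = solver or SolverConfig()
    rows = []
    for variant in variants:
        for pattern in patterns:
            spec = RunSpec.for_condition(
                pattern, variant, resolution=resolution, solver=solver,
                output_dir=(str(Path(output_dir) / f"{pattern}_{variant}")
                            if output_dir else None))
            try:
                res = run_single(spec)
                rows.append(res.summary)
            except Exception as err:  # keep the batch going
                rows.append({"pattern": pattern, "variant": variant,
                             "error": str(err)})
    df = pd.DataFrame(rows)
    if output_dir:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(output_dir) / "matrix_summary.csv", index=False)
    return df
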