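"""Run configuration: a fully serializable description of one simulation.

A :class:`RunSpec` nests the geometry, material, activation, mesh
resolution and solver settings, round-trips through YAML, and embeds every
modelling knob explicitly so each output bundle records exactly what was
run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .activation import ActivationField, default_field
from .geometry import GeometryParams, Resolution
from .materials import MaterialParams
from .solver import SolverConfig

__all__ = ["RunSpec", "load_spec", "save_spec"]


@dataclass(frozen=True)
class RunSpec:
    geometry: GeometryParams = GeometryParams()
    material: MaterialParams = MaterialParams()
    activation: ActivationField = ActivationField()
    resolution: Resolution = Resolution()
    solver: SolverConfig = SolverConfig()
    output_dir: Optional[str] = None
    tags: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tags"] = list(self.tags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunSpec":
        def build(klass, sub):
            if sub is None:
                return klass()
            kwargs = dict(sub)
            for key in ("yeoh_c", "fl_cos", "fl_sin"):
                if key in kwargs and kwargs[key] is not None:
                    kwargs[key] = tuple(kwargs[key])
            return klass(**kwargs)

        return cls(
            geometry=build(GeometryParams, d.get("geometry")),
            material=build(MaterialParams, d.get("material")),
            activation=build(ActivationField, d.get("activation")),
            resolution=build(Resolution, d.get("resolution")),
            solver=build(SolverConfig, d.get("solver")),
            output_dir=d.get("output_dir"),
            tags=tuple(d.get("tags", ())),
        )

    @classmethod
    def for_condition(cls, pattern: str, variant: str,
                      resolution: Resolution = Resolution(),
                      solver: SolverConfig = SolverConfig(),
                      output_dir: Optional[str] = None) -> "RunSpec":
        """Spec for one cell of the 4-pattern x 3-stiffness run matrix."""
        return cls(material=MaterialParams(apo_variant=variant),
                   activation=default_field(pattern),
                   resolution=resolution, solver=solver,
                   output_dir=output_dir,
                   tags=(pattern, variant))


def save_spec(spec: RunSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_spec(path) -> RunSpec:
    return RunSpec.from_dict(yaml.safe_load(Path(path).read_text()))
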