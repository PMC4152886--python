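"""Deterministic meshes and run specs at three sizes.

``unit``   - single-hexahedron specimens for constitutive/solver oracles;
``small``  - a coarse belly mesh that solves end-to-end in seconds, for
             symmetry and pipeline tests;
``default``- the production-scale belly mesh.
"""

from __future__ import annotations

import numpy as np

from .geometry import (GeometryParams, HexMesh, Region, Resolution,
                       generate_hex_mesh)
from .solver import SolverConfig

__all__ = ["make_fixtures", "single_hex_mesh", "SMALL_RESOLUTION",
           "DEFAULT_RESOLUTION"]

SMALL_RESOLUTION = Resolution(nx=2, ny_apo=1, ny_muscle=3, nz=6)
DEFAULT_RESOLUTION = Resolution(nx=8, ny_apo=2, ny_muscle=6, nz=48)


def single_hex_mesh(region: int = Region.MUSCLE, size: float = 1.0,
                    a0=(0.0, 0.0, 1.0)) -> HexMesh:
    """A unit cube of one material with a prescribed fiber direction.

    Built as a 1-cell structured mesh and then re-labelled, so it shares
    all machinery with the production meshes.
    """
    # Geometry numbers are irrelevant for a relabelled unit cube; build the
    # coarsest possible belly and overwrite coordinates.
    params = GeometryParams()
    mesh = generate_hex_mesh(params, Resolution(1, 1, 1, 1))
    # keep only the middle (muscle) cell and renumber
    keep = int(np.flatnonzero(mesh.cell_region == Region.MUSCLE)[0])
    nodes = mesh.hexes[keep]
    coords = np.array([
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float) * size
    mesh.node_coords = coords
    mesh.hexes = np.arange(8, dtype=np.int64)[None, :]
    mesh.cell_region = np.array([region], dtype=np.int8)
    mesh.cell_ijk = np.array([[0, 0, 0]])
    mesh.node_grid = None
    mesh.fiber_a0 = np.asarray(a0, dtype=float)[None, :]
    mesh.facet_sets = {}
    if hasattr(mesh, "_quad_cache"):
        delattr(mesh, "_quad_cache")
    return mesh


def make_fixtures(level: str = "small") -> dict:
    """Meshes and specs for the requested fixture size."""
    if level == "unit":
        return {
            "muscle_hex": single_hex_mesh(Region.MUSCLE),
            "apo_hex": single_hex_mesh(Region.APO_DEEP),
        }
    if level == "small":
        return {
            "resolution": SMALL_RESOLUTION,
            "mesh": generate_hex_mesh(GeometryParams(), SMALL_RESOLUTION),
            "solver": SolverConfig(n_load_steps=5),
        }
    if level == "default":
        return {
            "resolution": DEFAULT_RESOLUTION,
            "mesh": generate_hex_mesh(GeometryParams(), DEFAULT_RESOLUTION),
            "solver": SolverConfig(),
        }
    raise ValueError("level must be 'unit', 'small' or 'default'")
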