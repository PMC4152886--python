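"""Spatial-temporal activation fields alpha(X, t).

Four patterns are supported: ``uniform`` (every fiber at alpha_max = 0.1)
and three regionalized patterns (``proximal_distal``, ``midline``,
``medial_lateral``) in which half the muscle volume is driven to
alpha_max = 0.2 through a smooth arctan transition, so the volume-mean
activation of the whole muscle tissue always reaches 10% at the end of the
0.4 s linear ramp.

Region boundaries are calibrated against the actual mesh quadrature:

* proximal_distal: a z-plane placed so the mean spatial profile is 0.5;
* midline: a band in x centred on the mid-width plane, half-width
  calibrated the same way;
* medial_lateral: an x-plane at mid-width (which makes the mean exactly 0.5
  by symmetry) whose transition width is calibrated so the activity
  centroid sits at the reported x = 32.1 mm.

Aponeurosis tissue is never active.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .geometry import HexMesh, Region

__all__ = [
    "ActivationField",
    "PATTERNS",
    "spatial_profile",
    "alpha_at",
    "calibrate_region",
    "mean_activation",
]

PATTERNS = ("uniform", "proximal_distal", "midline", "medial_lateral")


@dataclass(frozen=True)
class ActivationField:
    """Activation pattern, level and ramp.

    ``boundary`` is the pattern's region parameter (z-plane position,
    band half-width, or x-plane position, all mm); ``transition_width`` is
    the arctan smoothing length (mm).  ``active_side`` selects which half is
    active for the split patterns ('low' = smaller coordinate; the default
    puts the proximal-distal active half adjacent to the fixed deep end).
    ``centroid_target`` (mm) is the activity-centroid constraint used to
    calibrate the medial-lateral transition width.
    """

    pattern: str = "uniform"
    alpha_max: float = 0.1
    ramp_duration: float = 0.4
    transition_width: float = 5.0
    boundary: Optional[float] = None
    active_side: str = "low"
    centroid_target: float = 32.1
    calibrated: bool = False

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"unknown activation pattern {self.pattern!r}; "
                f"choose from {PATTERNS}")
        if not 0.0 < self.alpha_max <= 1.0:
            raise ValueError("alpha_max must lie in (0, 1]")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        if self.active_side not in ("low", "high"):
            raise ValueError("active_side must be 'low' or 'high'")


def default_field(pattern: str) -> ActivationField:
    """Pattern with its standard peak level (0.1 uniform, 0.2 regionalized)."""
    amax = 0.1 if pattern == "uniform" else 0.2
    return ActivationField(pattern=pattern, alpha_max=amax)


def _smooth_step(d, width):
    """Arctan blend of a signed distance: 0.5 + arctan(d/w)/pi."""
    if width <= 0:
        return np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    return 0.5 + np.arctan(np.asarray(d, dtype=float) / width) / np.pi


def spatial_profile(points: np.ndarray, field: ActivationField) -> np.ndarray:
    """Spatial factor s(X) in [0, 1] at reference positions (n, 3) mm."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, z = pts[..., 0], pts[..., 2]
    sgn = 1.0 if field.active_side == "low" else -1.0
    if field.pattern == "uniform":
        return np.ones(x.shape)
    if field.boundary is None:
        raise ValueError("regionalized field must be calibrated first "
                         "(boundary is unset)")
    if field.pattern == "proximal_distal":
        d = sgn * (field.boundary - z)
    elif field.pattern == "midline":
        d = field.boundary - np.abs(x - 27.5)
    elif field.pattern == "medial_lateral":
        d = -sgn * (field.boundary - x)
    return _smooth_step(d, field.transition_width)


def alpha_at(points: np.ndarray, t: float, field: ActivationField,
             in_muscle: Optional[np.ndarray] = None) -> np.ndarray:
    """Activation alpha(X, t) = (t / ramp) * alpha_max * s(X).

    Points outside muscle tissue (``in_muscle`` False) return 0.
    """
    frac = np.clip(t / field.ramp_duration, 0.0, 1.0)
    a = frac * field.alpha_max * spatial_profile(points, field)
    if in_muscle is not None:
        a = np.where(in_muscle, a, 0.0)
    return a


def _muscle_quadrature(mesh: HexMesh):
    from .solver import quadrature_data
    qp_coords, detJ, _ = quadrature_data(mesh)
    muscle = mesh.cell_region == Region.MUSCLE
    return qp_coords[muscle].reshape(-1, 3), detJ[muscle].ravel()


def calibrate_region(field: ActivationField, mesh: HexMesh,
                     mean_tol: float = 0.01) -> ActivationField:
    """Place the region boundary so the muscle volume-mean of s(X) is 0.5.

    For the medial-lateral pattern the boundary is the mid-width plane
    (mean 0.5 by symmetry) and the transition width is solved so the
    activity centroid matches ``centroid_target``.  Raises if the smoothing
    is too wide to reach the mean within tolerance.
    """
    if field.pattern == "uniform":
        return replace(field, calibrated=True)
    pts, w = _muscle_quadrature(mesh)

    def mean_s(f):
        s = spatial_profile(pts, f)
        return float((s * w).sum() / w.sum())

    if field.pattern == "medial_lateral":
        f0 = replace(field, boundary=27.5)

        def centroid_err(width):
            f = replace(f0, transition_width=float(width))
            s = spatial_profile(pts, f)
            c = float((s * w * pts[:, 0]).sum() / (s * w).sum())
            return c - field.centroid_target

        wid = brentq(centroid_err, 1e-3, 200.0, xtol=1e-8)
        out = replace(f0, transition_width=float(wid), calibrated=True)
    else:
        if field.pattern == "proximal_distal":
            lo, hi = float(pts[:, 2].min()), float(pts[:, 2].max())
        else:  # midline band half-width
            lo, hi = 0.0, 27.5

        def mean_err(b):
            return mean_s(replace(field, boundary=float(b))) - 0.5

        if mean_err(lo) * mean_err(hi) > 0:
            raise ValueError("transition too wide: cannot reach mean "
                             "activation profile 0.5")
        b = brentq(mean_err, lo, hi, xtol=1e-10)
        out = replace(field, boundary=float(b), calibrated=True)
    if abs(mean_s(out) - 0.5) > mean_tol:
        raise ValueError("calibration failed to reach mean profile 0.5 "
                         f"within {mean_tol}")
    return out


def mean_activation(mesh: HexMesh, field: ActivationField, t: float) -> float:
    """Volume-weighted quadrature mean of alpha over muscle tissue."""
    pts, w = _muscle_quadrature(mesh)
    a = alpha_at(pts, t, field)
    return float((a * w).sum() / w.sum())


def activity_centroid_x(mesh: HexMesh, field: ActivationField) -> float:
    """x-coordinate of the activity-weighted centroid over muscle tissue."""
    pts, w = _muscle_quadrature(mesh)
    s = spatial_profile(pts, field)
    return float((s * w * pts[:, 0]).sum() / (s * w).sum())
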