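"""Continuous worm-body model built from a lattice of left/right marker pairs.

The model consists of three natural cubic splines — through the left lattice
points, the right lattice points, and the pair midpoints — sharing one
chord-length parameter so corresponding left/right/mid positions stay in
register.  The midline is reparameterized by arclength; sampling planes are
placed at uniform arclength steps, each carrying an orthonormal frame whose
left-right axis follows the interpolated lattice edges and therefore carries
any helical twist of the body.  Plane extents are clipped so neighbouring
planes never claim the same interior point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy.interpolate import CubicSpline, PchipInterpolator

from .io import Lattice

__all__ = [
    "WormModel",
    "SamplePlane",
    "DegenerateLatticeError",
    "FrameDegeneracyError",
    "build_model",
    "frame_at",
    "resolve_overlaps",
    "recommended_point_count",
    "save_model",
    "load_model",
]


class DegenerateLatticeError(ValueError):
    """Lattice cannot support a smooth midline (e.g. coincident midpoints)."""


class FrameDegeneracyError(ValueError):
    """Left-right direction is parallel to the tangent at some arclength."""


@dataclass
class SamplePlane:
    """One sampling plane normal to the midline.

    The frame ``{tangent, lr_axis, dv_axis}`` is right-handed orthonormal;
    ``lr_axis`` points left→right, ``dv_axis = tangent × lr_axis``.
    ``clip_bound`` is the in-plane radius (µm) this plane may claim after
    overlap resolution; it never exceeds ``half_extent``.
    """

    s: float
    center: np.ndarray
    tangent: np.ndarray
    lr_axis: np.ndarray
    dv_axis: np.ndarray
    half_extent: float
    clip_bound: float


@dataclass
class WormModel:
    lattice: Lattice
    step: float
    margin: float
    total_length: float
    samples: list[SamplePlane] = field(repr=False)
    # internal spline machinery
    _mid: CubicSpline = field(repr=False)
    _left: CubicSpline = field(repr=False)
    _right: CubicSpline = field(repr=False)
    _u_of_s: PchipInterpolator = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.samples])

    def midline_point(self, s: float | np.ndarray) -> np.ndarray:
        """Midline position at arclength ``s`` (µm from the nose)."""
        return self._mid(self._u_of_s(s))


def _chord_param(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise DegenerateLatticeError("consecutive pair midpoints coincide")
    return np.concatenate([[0.0], np.cumsum(seg)])


def _arclength_table(mid: CubicSpline, u_knots: np.ndarray, n_sub: int = 24):
    """Cumulative arclength s(u) on a dense grid via per-interval Gauss quadrature."""
    gx, gw = np.polynomial.legendre.leggauss(6)
    u_dense = [0.0]
    s_dense = [0.0]
    s_acc = 0.0
    for a, b in zip(u_knots[:-1], u_knots[1:]):
        edges = np.linspace(a, b, n_sub + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mid_u = 0.5 * (lo + hi)
            half = 0.5 * (hi - lo)
            speeds = np.linalg.norm(mid(mid_u + half * gx, 1), axis=1)
            s_acc += half * float(np.dot(gw, speeds))
            u_dense.append(hi)
            s_dense.append(s_acc)
    return np.array(u_dense), np.array(s_dense)


def build_model(l: Lattice, step: float = 0.5, margin: float = 1.2,
                resolve: bool = True) -> WormModel:
    """Build the continuous worm model from a lattice.

    Parameters
    ----------
    l
        Ordered left/right marker pairs, nose first.
    step
        Arclength spacing between sampling planes, µm.
    margin
        Plane half-extent as a multiple of the local body half-width
        (1.2 covers hypodermis beyond the seam nuclei).
    resolve
        Clip plane extents against neighbours and local curvature
        (see :func:`resolve_overlaps`).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if margin < 1:
        raise ValueError("margin must be >= 1")
    if len(l) < 2:
        raise DegenerateLatticeError("at least 2 lattice pairs are required")

    mids = l.midpoints
    u = _chord_param(mids)
    mid = CubicSpline(u, mids, bc_type="not-a-knot")
    left = CubicSpline(u, l.left, bc_type="not-a-knot")
    right = CubicSpline(u, l.right, bc_type="not-a-knot")

    u_dense, s_dense = _arclength_table(mid, u)
    # adaptive quadrature for the total length (the dense table seeds it)
    total_length = 0.0
    for a, b in zip(u[:-1], u[1:]):
        val, _ = integrate.quad(lambda x: float(np.linalg.norm(mid(x, 1))),
                                a, b, epsrel=1e-9, limit=200)
        total_length += val
    s_dense *= total_length / s_dense[-1]
    u_of_s = PchipInterpolator(s_dense, u_dense)

    model = WormModel(lattice=l, step=step, margin=margin,
                      total_length=total_length, samples=[],
                      _mid=mid, _left=left, _right=right, _u_of_s=u_of_s)

    n = int(np.floor(total_length / step + 1e-9)) + 1
    s_vals = np.arange(n) * step
    planes = []
    for s in s_vals:
        t, lr, dv = frame_at(model, float(s))
        uu = float(u_of_s(s))
        c = mid(uu)
        hw = max(np.linalg.norm(left(uu) - c), np.linalg.norm(right(uu) - c))
        he = margin * float(hw)
        planes.append(SamplePlane(s=float(s), center=np.asarray(c, float),
                                  tangent=t, lr_axis=lr, dv_axis=dv,
                                  half_extent=he, clip_bound=he))
    model.samples = planes
    if resolve:
        model = resolve_overlaps(model)
    return model


def frame_at(model: WormModel, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame ``(tangent, lr_axis, dv_axis)`` at arclength ``s``.

    The left-right axis is the interpolated right-edge minus left-edge
    direction with its tangential component removed; it carries the helical
    twist of the body.  ``dv_axis = tangent × lr_axis`` completes a
    right-handed frame.
    """
    if not (-1e-9 <= s <= model.total_length + 1e-9):
        raise ValueError(f"arclength {s} outside [0, {model.total_length}]")
    u = float(model._u_of_s(np.clip(s, 0, model.total_length)))
    d = model._mid(u, 1)
    t = d / np.linalg.norm(d)
    raw = model._right(u) - model._left(u)
    raw = raw / np.linalg.norm(raw)
    lr = raw - np.dot(raw, t) * t
    norm = np.linalg.norm(lr)
    if norm < 1e-6:
        raise FrameDegeneracyError(
            f"left-right direction parallel to tangent at s={s:.3f} µm")
    lr = lr / norm
    dv = np.cross(t, lr)
    return t, lr, dv


def _curvature_radius(model: WormModel, u: float) -> float:
    d1 = model._mid(u, 1)
    d2 = model._mid(u, 2)
    num = np.linalg.norm(np.cross(d1, d2))
    if num < 1e-12:
        return np.inf
    return float(np.linalg.norm(d1) ** 3 / num)


def resolve_overlaps(model: WormModel) -> WormModel:
    """Clip each plane so it cannot cross into a neighbour's territory.

    Two constraints shrink the in-plane radius: (i) the plane must not
    cross the bisector plane between its center and either neighbouring
    plane center, and (ii) it must not extend past the local radius of
    curvature of the midline (planes through a circle's center intersect
    there).  With both applied, every interior point is claimed by exactly
    one plane under the nearest-center rule.
    """
    planes = model.samples
    for k, p in enumerate(planes):
        bound = p.half_extent
        bound = min(bound, _curvature_radius(model, float(model._u_of_s(p.s))))
        for j in (k - 1, k + 1):
            if 0 <= j < len(planes):
                delta = planes[j].center - p.center
                dist = np.linalg.norm(delta)
                if dist < 1e-12:
                    continue
                n = delta / dist
                # in-plane reach towards the bisector plane at dist/2
                proj = np.hypot(np.dot(p.lr_axis, n), np.dot(p.dv_axis, n))
                if proj > 1e-9:
                    bound = min(bound, 0.5 * dist / proj)
        p.clip_bound = max(float(bound), 1e-9)
    return model


def recommended_point_count(n_seam_pairs: int, n_bends: int) -> int:
    """Minimum recommended lattice point count for manual lattice building.

    Two points per seam-cell pair, a pair marking the nose, and one extra
    pair for every bend between seam cells: ``2·n_seam_pairs + 2 + 2·B``.
    """
    if n_seam_pairs < 0 or n_bends < 0:
        raise ValueError("counts must be non-negative")
    return 2 * n_seam_pairs + 2 + 2 * n_bends


# --------------------------------------------------------------------------- #
# serialization (JSON sidecar: lattice + build parameters, model is rebuilt)
# --------------------------------------------------------------------------- #

def save_model(model: WormModel, path: str | Path) -> None:
    obj = {
        "left": model.lattice.left.tolist(),
        "right": model.lattice.right.tolist(),
        "labels": model.lattice.labels,
        "step": model.step,
        "margin": model.margin,
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_model(path: str | Path) -> WormModel:
    obj = json.loads(Path(path).read_text())
    lat = Lattice(np.array(obj["left"]), np.array(obj["right"]), obj.get("labels"))
    return build_model(lat, step=obj["step"], margin=obj["margin"])
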