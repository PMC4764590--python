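"""Resampling twisted volumes into the straightened frame and mapping points.

Untwisted-frame convention: ``x`` = lateral (left negative, right positive),
``y`` = dorso-ventral, ``z`` = arclength from the nose.  Each sampling plane
of the worm model contributes one output slice; slices are concatenated
nose→tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .io import Annotation, AnnotationTable, Volume
from .model import WormModel

__all__ = [
    "StraightenedVolume",
    "straighten_volume",
    "map_point_to_untwisted",
    "map_points_to_untwisted",
    "map_point_to_twisted",
    "transform_annotations",
]


@dataclass
class StraightenedVolume(Volume):
    """A straightened volume plus provenance of the resampling run."""

    model: WormModel | None = None
    W: float = 0.0          # output half-width, µm


def _plane_tree(model: WormModel) -> cKDTree:
    tree = getattr(model, "_plane_tree", None)
    if tree is None:
        tree = cKDTree(model.centers())
        model._plane_tree = tree
    return tree


def straighten_volume(v: Volume, model: WormModel, W: float | None = None) -> StraightenedVolume:
    """Resample a twisted volume into the straightened frame.

    Output voxel ``(i, j, k)`` is the trilinear interpolation of ``v`` at
    ``center_k + (i·step − W)·lr_axis_k + (j·step − W)·dv_axis_k``; positions
    outside the input volume or outside a plane's clip bound are zero.

    Parameters
    ----------
    v
        Twisted input volume.
    model
        Worm model built on the same world coordinates as ``v``.
    W
        Output half-width in µm; defaults to ``margin`` × the model's
        largest half-width.
    """
    if model.n_samples == 0:
        raise ValueError("model has no sampling planes")
    step = model.step
    if W is None:
        W = model.margin * max(p.half_extent / model.margin for p in model.samples)
    half_n = int(np.ceil(W / step))
    nxy = 2 * half_n + 1
    offs = (np.arange(nxy) - half_n) * step          # lateral offsets, µm

    nz, ny, nx = v.intensities.shape
    out = np.zeros((model.n_samples, nxy, nxy), dtype=np.float32)
    ii, jj = np.meshgrid(offs, offs, indexing="xy")  # jj rows = y, ii cols = x
    r2 = ii ** 2 + jj ** 2

    for k, p in enumerate(model.samples):
        pos = (p.center[None, None, :]
               + ii[:, :, None] * p.lr_axis[None, None, :]
               + jj[:, :, None] * p.dv_axis[None, None, :])
        vox = pos / v.voxel_size                     # (y, x, 3) in (x,y,z) order
        coords = np.stack([vox[..., 2], vox[..., 1], vox[..., 0]])
        slab = map_coordinates(v.intensities.astype(np.float32), coords,
                               order=1, mode="constant", cval=0.0)
        slab[r2 > p.clip_bound ** 2] = 0.0
        out[k] = slab

    sv = StraightenedVolume(intensities=out, voxel_size=step,
                            channel_label=v.channel_label, model=model, W=float(W))
    return sv


def map_points_to_untwisted(model: WormModel, pts: np.ndarray) -> np.ndarray:
    """Map twisted-frame points into the untwisted frame.

    Each point is claimed by the sampling plane with the nearest center
    (ties broken toward smaller arclength) provided its in-plane radius is
    within the plane's clip bound and it lies within one step of the plane
    along the tangent.  Unclaimed points map to NaN.

    Returns an ``(n, 3)`` array of untwisted ``(x, y, z)`` µm.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    tree = _plane_tree(model)
    _, idx = tree.query(pts)
    out = np.full_like(pts, np.nan)
    last = model.n_samples - 1
    for i, (p, k) in enumerate(zip(pts, idx)):
        plane = model.samples[int(k)]
        d = p - plane.center
        ax = np.dot(d, plane.tangent)
        x = np.dot(d, plane.lr_axis)
        y = np.dot(d, plane.dv_axis)
        # axial tolerance: one step between planes; at the nose/tail end
        # planes the outward tolerance widens to the clip radius so the
        # rounded body cap is still claimed
        lo = -model.step if k > 0 else -plane.clip_bound
        hi = model.step if k < last else plane.clip_bound
        if np.hypot(x, y) <= plane.clip_bound + 1e-9 and lo - 1e-9 <= ax <= hi + 1e-9:
            out[i] = (x, y, plane.s)
    return out


def map_point_to_untwisted(model: WormModel, p) -> tuple[float, float, float] | None:
    """Single-point version of :func:`map_points_to_untwisted`; None if unclaimed."""
    q = map_points_to_untwisted(model, np.asarray(p, dtype=float))[0]
    if np.any(np.isnan(q)):
        return None
    return float(q[0]), float(q[1]), float(q[2])


def map_point_to_twisted(model: WormModel, q) -> np.ndarray:
    """Inverse mapping: untwisted ``(x, y, z)`` back to twisted-frame µm.

    ``z`` must lie within ``[0, total_length]``; the point is reconstructed
    on the nearest sampling plane, so the round trip
    twisted → untwisted → twisted errs by less than one step.
    """
    q = np.asarray(q, dtype=float).reshape(3)
    if not (-1e-9 <= q[2] <= model.total_length + 1e-9):
        raise ValueError(
            f"untwisted z={q[2]} outside [0, {model.total_length:.3f}] µm")
    k = int(np.clip(round(q[2] / model.step), 0, model.n_samples - 1))
    p = model.samples[k]
    return p.center + q[0] * p.lr_axis + q[1] * p.dv_axis


def transform_annotations(a: AnnotationTable, model: WormModel) -> AnnotationTable:
    """Map all annotations to the untwisted frame, relative to the origin.

    The designated origin (conventionally the nose) must be claimed by the
    model; its untwisted position is subtracted from every row so all output
    coordinates are origin-relative.  Rows outside the body keep their
    twisted coordinates and are flagged unclaimed rather than dropped.
    """
    origin = a.origin    # raises if not designated
    o_u = map_point_to_untwisted(model, origin.point)
    if o_u is None:
        raise ValueError(f"origin {origin.name!r} is not claimed by the model")
    o_u = np.asarray(o_u)

    rows = []
    for r in a.rows:
        u = map_point_to_untwisted(model, r.point)
        if u is None:
            rows.append(Annotation(name=r.name, point=r.point.copy(),
                                   frame=r.frame, untwisted=None, claimed=False))
        else:
            rows.append(Annotation(name=r.name, point=r.point.copy(),
                                   frame=r.frame,
                                   untwisted=np.asarray(u) - o_u, claimed=True))
    return AnnotationTable(rows=rows, origin_name=a.origin_name)
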