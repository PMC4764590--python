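"""Morphology-preservation and inter-embryo variability statistics.

The untwisting controls compare, per embryo, a metric series measured in the
twisted frame against the same metric in the untwisted frame: the mean and
SD of the absolute difference across time (μ_diff,time, σ_diff,time) are
computed per embryo, then averaged across embryos into population values
(<μ>_embryo, <σ>_embryo).  Sample (n−1) standard deviations are used
throughout, and SDs are averaged (not variance-pooled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryTable

__all__ = [
    "StatsSummary",
    "pair_distance_series",
    "contour_length",
    "compare_frames",
    "positional_variability",
]


@dataclass
class StatsSummary:
    """Nested population statistics of twisted-vs-untwisted differences."""

    per_embryo: list[tuple[float, float]]     # (mu_diff_time, sigma_diff_time)
    population_mu: float                      # <mu_diff,time>_embryo
    population_sigma: float                   # <sigma_diff,time>_embryo
    max_single_timepoint_diff: float          # µm


def pair_distance_series(points_L, points_R) -> np.ndarray:
    """Per-timepoint Euclidean distance between a left/right point pair."""
    L = np.asarray(points_L, dtype=float).reshape(-1, 3)
    R = np.asarray(points_R, dtype=float).reshape(-1, 3)
    if len(L) != len(R):
        raise ValueError(f"series lengths differ: {len(L)} vs {len(R)}")
    return np.linalg.norm(L - R, axis=1)


def contour_length(points) -> float:
    """Summed consecutive segment lengths of an ordered 3D polyline, µm."""
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < 2:
        raise ValueError("contour length needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def compare_frames(twisted: list[np.ndarray], untwisted: list[np.ndarray]) -> StatsSummary:
    """Population statistics of |twisted − untwisted| metric differences.

    Parameters
    ----------
    twisted, untwisted
        One per-timepoint metric series per embryo (paired lists).
    """
    if len(twisted) == 0:
        raise ValueError("at least one embryo is required")
    if len(twisted) != len(untwisted):
        raise ValueError("twisted and untwisted lists must be paired per embryo")
    per = []
    global_max = 0.0
    for tw, un in zip(twisted, untwisted):
        tw = np.asarray(tw, dtype=float)
        un = np.asarray(un, dtype=float)
        if tw.shape != un.shape:
            raise ValueError("paired series must have equal length")
        diff = np.abs(tw - un)
        mu = float(np.mean(diff))
        sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
        per.append((mu, sd))
        global_max = max(global_max, float(np.max(diff)))
    return StatsSummary(
        per_embryo=per,
        population_mu=float(np.mean([m for m, _ in per])),
        population_sigma=float(np.mean([s for _, s in per])),
        max_single_timepoint_diff=global_max,
    )


def positional_variability(aligned: TrajectoryTable,
                           seam_cells: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Inter-embryo positional variability of aligned trajectories.

    For each cell and coordinate, the SD across embryos is computed at every
    timepoint with ≥ 2 embryos present, then averaged over time
    (<σX>_time etc.).  Grand means over the seam-cell names
    (<<σX>_time>_seam cell ...) are returned alongside.

    Returns
    -------
    per_cell
        DataFrame indexed by cell with columns ``sigma_X, sigma_Y, sigma_Z``.
    grand
        ``{"X": ..., "Y": ..., "Z": ...}`` means over seam cells.
    """
    df = aligned.data
    records = {}
    for cell, grp in df.groupby("cell"):
        sds = {}
        for coord in ("X", "Y", "Z"):
            wide = grp.pivot_table(index="time_min", columns="embryo",
                                   values=coord, dropna=False)
            counts = wide.notna().sum(axis=1)
            sd_t = wide.std(axis=1, ddof=1)[counts >= 2]   # timepoints with <2 embryos excluded
            sds[f"sigma_{coord}"] = float(sd_t.mean()) if len(sd_t) else np.nan
        records[cell] = sds
    per_cell = pd.DataFrame.from_dict(records, orient="index").sort_index()

    if seam_cells is None:
        from .synthetic import SEAM_PAIR_ORDER
        seam_cells = [c for c in per_cell.index
                      if any(c.startswith(s) for s in SEAM_PAIR_ORDER)]
    sub = per_cell.loc[[c for c in seam_cells if c in per_cell.index]]
    grand = {c: float(sub[f"sigma_{c}"].mean()) for c in ("X", "Y", "Z")}
    return per_cell, grand
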