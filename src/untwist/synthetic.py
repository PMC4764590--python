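"""Synthetic twisted embryo phantoms and multi-embryo trajectory sets.

Phantoms are built from closed-form geometry — centerlines composed of
straight and circular-arc segments, a linear helical twist of the left-right
axis about the midline, and a tapered body radius — so every geometric
quantity the rest of the package estimates (arclength, twist angle, marker
positions, untwisted coordinates) has an analytic ground truth.

Trajectory sets emulate the landmark motions of an elongating embryo:
axial (Z) positions follow three-parameter logistic growth, lateral (X)
positions a power law drifting toward the midline, dorso-ventral (Y)
positions a shallow line, with configurable per-embryo temporal shifts,
Gaussian noise, and injected outliers/gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Annotation, AnnotationTable, Lattice, TrajectoryTable, Volume

__all__ = [
    "PhantomWorm",
    "PhantomTruth",
    "make_phantom",
    "TrajectoryTruth",
    "make_trajectory_set",
    "SEAM_PAIR_ORDER",
]

#: Anterior→posterior order of seam-cell pair names (Q is V5's anterior daughter).
SEAM_PAIR_ORDER = ["H0", "H1", "H2", "V1", "V2", "V3", "V4", "V5", "V6", "T"]


# --------------------------------------------------------------------------- #
# phantom geometry
# --------------------------------------------------------------------------- #

class PhantomWorm:
    """Closed-form twisted worm-body geometry.

    The centerline is a chain of planar (x–z plane) segments, each either
    straight or a circular arc; the cumulative in-plane heading is therefore
    piecewise linear in arclength and every position/frame is analytic.
    A linear twist rotates the left-right axis about the tangent by
    ``twist_total`` radians over the full length.

    Parameters
    ----------
    length
        Total arclength, µm.
    bend_angle
        Total in-plane bend, radians (a single arc by default).
    twist_total
        Total helical twist of the left-right axis, radians.
    r_head, r_tail
        Body half-width at nose and tail ends, µm (linear taper — the
        "tadpole" profile of a pre-elongation embryo).
    segments
        Optional explicit chain ``[(length_fraction, bend_angle_rad), ...]``
        overriding the single-arc default; fractions must sum to 1.
    offset
        World position of the nose, µm.
    """

    def __init__(self, length: float = 120.0, bend_angle: float = np.pi,
                 twist_total: float = np.pi, r_head: float = 11.0,
                 r_tail: float = 8.0,
                 segments: list[tuple[float, float]] | None = None,
                 offset=(0.0, 0.0, 0.0)):
        if length <= 0:
            raise ValueError("length must be > 0")
        self.length = float(length)
        self.twist_total = float(twist_total)
        self.r_head = float(r_head)
        self.r_tail = float(r_tail)
        self.offset = np.asarray(offset, dtype=float)
        if segments is None:
            segments = [(1.0, float(bend_angle))]
        fr = sum(f for f, _ in segments)
        if not np.isclose(fr, 1.0):
            raise ValueError("segment length fractions must sum to 1")
        # precompute segment boundaries, headings and start positions
        self._seg_s0, self._seg_len, self._seg_ang = [], [], []
        self._seg_th0, self._seg_p0 = [], []
        s0, th, p = 0.0, 0.0, np.zeros(3)
        for f, ang in segments:
            seg_l = f * self.length
            self._seg_s0.append(s0)
            self._seg_len.append(seg_l)
            self._seg_ang.append(float(ang))
            self._seg_th0.append(th)
            self._seg_p0.append(p.copy())
            p = p + self._seg_disp(seg_l, seg_l, th, ang)
            th += ang
            s0 += seg_l
        self._check_realizable()

    # -- internal closed-form pieces ------------------------------------- #

    @staticmethod
    def _seg_disp(s, seg_l, th0, ang):
        """Displacement after arclength s into a segment starting with heading th0."""
        if abs(ang) < 1e-12:
            return s * np.array([np.sin(th0), 0.0, np.cos(th0)])
        R = seg_l / ang
        th1 = th0 + ang * s / seg_l
        return R * np.array([np.cos(th0) - np.cos(th1), 0.0,
                             np.sin(th1) - np.sin(th0)])

    def _segment_of(self, s):
        s = np.clip(s, 0.0, self.length)
        i = len(self._seg_s0) - 1
        while i > 0 and s < self._seg_s0[i] - 1e-12:
            i -= 1
        return i, s - self._seg_s0[i]

    def heading(self, s: float) -> float:
        """In-plane heading angle θ(s) of the tangent (radians from +z)."""
        i, ds = self._segment_of(s)
        frac = ds / self._seg_len[i] if self._seg_len[i] > 0 else 0.0
        return self._seg_th0[i] + self._seg_ang[i] * frac

    def centerline(self, s):
        """Centerline position at arclength s (scalar or array), world µm."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s_arr), 3))
        for k, sv in enumerate(s_arr):
            i, ds = self._segment_of(sv)
            out[k] = (self._seg_p0[i]
                      + self._seg_disp(ds, self._seg_len[i], self._seg_th0[i],
                                       self._seg_ang[i]))
        out += self.offset
        return out[0] if np.isscalar(s) or np.ndim(s) == 0 else out

    def twist(self, s) -> float:
        """Cumulative twist angle at arclength s (linear by default)."""
        return self.twist_total * np.asarray(s, dtype=float) / self.length

    def radius(self, s):
        """Body half-width at arclength s (linear taper head→tail)."""
        f = np.asarray(s, dtype=float) / self.length
        return self.r_head + (self.r_tail - self.r_head) * f

    def frame(self, s: float):
        """Twisted frame (tangent, lr_axis, dv_axis) at arclength s."""
        th = self.heading(s)
        T = np.array([np.sin(th), 0.0, np.cos(th)])
        N = np.array([np.cos(th), 0.0, -np.sin(th)])   # in-plane normal
        B = np.array([0.0, 1.0, 0.0])                  # T × N
        phi = float(self.twist(s))
        lr = np.cos(phi) * N + np.sin(phi) * B
        dv = np.cross(T, lr)
        return T, lr, dv

    def point(self, s: float, x: float, y: float) -> np.ndarray:
        """World position of untwisted coordinates (x lateral, y dv, s axial)."""
        _, lr, dv = self.frame(s)
        return self.centerline(float(s)) + x * lr + y * dv

    def _check_realizable(self):
        for i, ang in enumerate(self._seg_ang):
            if abs(ang) > 1e-9:
                R = self._seg_len[i] / abs(ang)
                s_mid = self._seg_s0[i] + 0.5 * self._seg_len[i]
                if float(self.radius(s_mid)) >= R:
                    raise ValueError(
                        f"body radius {float(self.radius(s_mid)):.1f} µm exceeds "
                        f"the centerline radius of curvature {R:.1f} µm — "
                        "phantom not physically realizable")


@dataclass
class PhantomTruth:
    """Ground truth for a synthetic phantom embryo."""

    worm: PhantomWorm
    seed: int
    pair_s: np.ndarray                       # arclengths of lattice pairs
    lattice: Lattice                         # true left/right pairs
    marker_names: list[str]                  # seam nuclei: H0L, H0R, ...
    marker_pos: np.ndarray                   # (n, 3) twisted world µm
    marker_untwisted: np.ndarray             # (n, 3) true untwisted (x, y, s)
    pharynx_twisted: np.ndarray              # (m, 3) polyline, twisted µm
    pharynx_untwisted: np.ndarray            # (m, 3) true untwisted coords
    neurite: dict[str, np.ndarray] = field(default_factory=dict)


def _truth_markers(worm: PhantomWorm, n_pairs: int):
    pair_s = np.linspace(0.0, worm.length, n_pairs)
    left, right, names, pos, upos = [], [], [], [], []
    labels = (SEAM_PAIR_ORDER if n_pairs == len(SEAM_PAIR_ORDER)
              else [f"P{i}" for i in range(n_pairs)])
    for s, lab in zip(pair_s, labels):
        r = float(worm.radius(s))
        L = worm.point(s, -r, 0.0)
        R = worm.point(s, +r, 0.0)
        left.append(L)
        right.append(R)
        names += [lab + "L", lab + "R"]
        pos += [L, R]
        upos += [np.array([-r, 0.0, s]), np.array([+r, 0.0, s])]
    lat = Lattice(np.array(left), np.array(right), labels=list(labels))
    return pair_s, lat, names, np.array(pos), np.array(upos)


def make_phantom(n_pairs: int = 10, length: float = 120.0,
                 bend_angle: float = np.pi, twist_total: float = np.pi,
                 r_head: float = 11.0, r_tail: float = 8.0,
                 segments: list[tuple[float, float]] | None = None,
                 voxel_size: float = 1.0, noise_snr: float = 10.0,
                 blob_sigma: float = 1.0, shell_amp: float = 0.3,
                 render: bool = True, seed: int = 0,
                 ) -> tuple[Volume | None, Lattice, AnnotationTable, PhantomTruth]:
    """Generate a twisted phantom embryo with full ground truth.

    Returns ``(volume, lattice, annotations, truth)``.  The volume is the sum
    of Gaussian blobs (σ = ``blob_sigma``) at the seam-nucleus positions, a
    soft tube-shell intensity along the body wall, and Gaussian noise with
    peak-signal-to-noise ``noise_snr`` (``noise_snr=inf`` for noiseless).
    With ``render=False`` only the geometry/truth outputs are produced,
    which is cheap at any body size.
    """
    worm = PhantomWorm(length=length, bend_angle=bend_angle,
                       twist_total=twist_total, r_head=r_head, r_tail=r_tail,
                       segments=segments)
    # place the worm in the positive octant with a margin for rendering
    pad = max(r_head, r_tail) + 4 * blob_sigma
    dense_s = np.linspace(0, worm.length, 400)
    cl = worm.centerline(dense_s)
    worm.offset = worm.offset + (pad - cl.min(axis=0))
    cl = cl + (pad - cl.min(axis=0))

    pair_s, lat, names, pos, upos = _truth_markers(worm, n_pairs)

    # pharynx-like polyline: nose to one-third body length, near the midline
    ph_s = np.linspace(0.0, worm.length / 3.0, 30)
    ph_tw, ph_un = [], []
    for j, s in enumerate(ph_s):
        # the pharynx is a body structure: its offset is (nearly) fixed in
        # body coordinates, drifting only slowly around the axis
        rr = 0.25 * float(worm.radius(s))
        psi = 0.2 + 0.05 * j
        x, y = rr * np.cos(psi), rr * np.sin(psi)
        ph_tw.append(worm.point(s, x, y))
        ph_un.append([x, y, s])
    ph_tw, ph_un = np.array(ph_tw), np.array(ph_un)

    # three-point neurite set (cell body, ventral→posterior turn, terminus)
    neur = {
        "ALA": worm.point(0.15 * worm.length, 0.0, 0.35 * worm.radius(0.15 * worm.length)),
        "AxR1": worm.point(0.18 * worm.length, 0.3 * worm.radius(0.18 * worm.length), 0.0),
        "AxR2": worm.point(0.45 * worm.length, 0.3 * worm.radius(0.45 * worm.length), 0.0),
    }

    ann_rows = [Annotation(name="nose", point=worm.centerline(0.0))]
    ann_rows += [Annotation(name=n, point=p) for n, p in zip(names, pos)]
    ann_rows += [Annotation(name=k, point=v) for k, v in neur.items()]
    ann = AnnotationTable(rows=ann_rows, origin_name="nose")

    truth = PhantomTruth(worm=worm, seed=seed, pair_s=pair_s, lattice=lat,
                         marker_names=names, marker_pos=pos,
                         marker_untwisted=upos, pharynx_twisted=ph_tw,
                         pharynx_untwisted=ph_un, neurite=neur)

    vol = _render_volume(worm, pos, voxel_size, noise_snr, blob_sigma,
                         shell_amp, seed) if render else None
    return vol, lat, ann, truth


def _render_volume(worm, blob_pos, voxel_size, noise_snr, blob_sigma,
                   shell_amp, seed) -> Volume:
    dense_s = np.linspace(0, worm.length, max(200, int(worm.length / voxel_size) * 2))
    cl = worm.centerline(dense_s)
    pad = max(worm.r_head, worm.r_tail) + 4 * blob_sigma
    hi = (cl.max(axis=0) + pad)
    shape = np.ceil(hi / voxel_size).astype(int) + 1      # (x, y, z) counts
    nz, ny, nx = int(shape[2]), int(shape[1]), int(shape[0])
    img = np.zeros((nz, ny, nx), dtype=np.float32)

    # seam-nucleus blobs: Gaussian splat on a local patch
    half = int(np.ceil(4 * blob_sigma / voxel_size))
    for p in blob_pos:
        cx, cy, cz = (p / voxel_size)
        x0, y0, z0 = int(round(cx)), int(round(cy)), int(round(cz))
        zs = np.arange(max(z0 - half, 0), min(z0 + half + 1, nz))
        ys = np.arange(max(y0 - half, 0), min(y0 + half + 1, ny))
        xs = np.arange(max(x0 - half, 0), min(x0 + half + 1, nx))
        if len(zs) == 0 or len(ys) == 0 or len(xs) == 0:
            continue
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        d2 = ((X * voxel_size - p[0]) ** 2 + (Y * voxel_size - p[1]) ** 2
              + (Z * voxel_size - p[2]) ** 2)
        img[np.ix_(zs, ys, xs)] += np.exp(-d2 / (2 * blob_sigma ** 2)).astype(np.float32)

    # soft body-wall shell via nearest centerline sample
    if shell_amp > 0:
        tree = cKDTree(cl)
        Z, Y, X = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                              indexing="ij")
        vox = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) * voxel_size
        d, idx = tree.query(vox, distance_upper_bound=max(worm.r_head, worm.r_tail) + 3)
        ok = np.isfinite(d)
        r_local = worm.radius(dense_s[np.clip(idx[ok], 0, len(dense_s) - 1)])
        shell = np.zeros(len(vox), dtype=np.float32)
        shell[ok] = shell_amp * np.exp(-((d[ok] - r_local) / 0.9) ** 2)
        img += shell.reshape(nz, ny, nx)

    if np.isfinite(noise_snr):
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, 1.0 / noise_snr, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return Volume(intensities=img, voxel_size=voxel_size,
                  channel_label="phantom")


# --------------------------------------------------------------------------- #
# trajectory sets
# --------------------------------------------------------------------------- #

def _logistic3(t, A, B, C):
    return A / (1.0 + np.exp(-B * (t - C)))


def _power(t, a, b, c):
    return a * np.power(np.maximum(t, 1e-9), b) + c


def default_cell_models(n_seam: int = 10) -> dict[str, dict]:
    """Per-cell generating models echoing an elongating embryo.

    Axial (Z) positions follow three-parameter logistic growth with upper
    asymptotes spread from ~24 µm (H0) to ~160 µm (T) — the embryo elongates
    from roughly 86 to 162 µm nose-to-tail; lateral (X) positions drift
    inward as a power law from ~11 toward ~8 µm half-width; dorso-ventral
    (Y) positions stay nearly flat.
    """
    cells = {}
    names = SEAM_PAIR_ORDER[:n_seam]
    A_vals = np.linspace(24.0, 160.0, len(names))
    for name, A in zip(names, A_vals):
        cells[name] = {
            "X": ("power", {"a": -0.12, "b": 0.8, "c": 11.0}),
            "Y": ("linear", {"p1": -0.004, "p2": 3.0}),
            "Z": ("logistic3", {"A": float(A), "B": 0.08, "C": 100.0}),
        }
    return cells


@dataclass
class TrajectoryTruth:
    cells: dict[str, dict]
    true_shifts: list[int]
    dt: list[float]
    dt_ref: float
    noise_sd: float
    outliers: list[tuple]        # (embryo, cell, coord, index, delta)
    gaps: list[tuple]            # (embryo, cell, coord, index)


def make_trajectory_set(n_embryos: int = 5, cells: dict | None = None,
                        true_shifts: list[int] | None = None,
                        dt: float | list[float] = 2.5,
                        n_time: int = 100, noise_sd: float = 2.0,
                        n_outliers: int = 0, n_gaps: int = 0,
                        seed: int = 0) -> tuple[TrajectoryTable, TrajectoryTruth]:
    """Simulate per-cell coordinate trajectories for several embryos.

    Each embryo's series are generated from the per-cell parametric models,
    with the logistic inflection (and the whole time course) delayed by
    ``true_shifts[e]`` reference timepoints, plus iid Gaussian noise of SD
    ``noise_sd`` µm.  Optional spikes (+30 µm outliers) and gaps (NaN) are
    injected at random indices for cleaning tests.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    if cells is None:
        cells = default_cell_models()
    if true_shifts is None:
        true_shifts = [0] * n_embryos
    if np.isscalar(dt):
        dt = [float(dt)] * n_embryos
    dt_ref = min(dt)
    rng = np.random.default_rng(seed)

    rows = []
    outliers, gaps = [], []
    for e in range(n_embryos):
        t = np.arange(n_time) * dt[e]
        t_shift = true_shifts[e] * dt_ref
        for cname, spec in cells.items():
            coords = {}
            for coord in ("X", "Y", "Z"):
                fam, par = spec[coord]
                # embryo e runs ahead by its shift: aligning it back onto the
                # reference requires shifting it true_shifts[e] timepoints right
                tt = t + t_shift
                if fam == "logistic3":
                    y = _logistic3(tt, par["A"], par["B"], par["C"])
                elif fam == "power":
                    y = _power(np.maximum(tt, 0.0), par["a"], par["b"], par["c"])
                elif fam == "linear":
                    y = par["p1"] * tt + par["p2"]
                else:
                    raise ValueError(f"unknown generator family {fam!r}")
                if noise_sd > 0:
                    y = y + rng.normal(0.0, noise_sd, size=len(y))
                coords[coord] = y
            rows.append(pd.DataFrame({
                "embryo": e, "cell": cname, "time_min": t,
                "X": coords["X"], "Y": coords["Y"], "Z": coords["Z"]}))
    df = pd.concat(rows, ignore_index=True)

    for _ in range(n_outliers):
        i = int(rng.integers(0, len(df)))
        coord = ("X", "Y", "Z")[int(rng.integers(0, 3))]
        df.loc[i, coord] += 30.0
        outliers.append((df.loc[i, "embryo"], df.loc[i, "cell"], coord,
                         int(i), 30.0))
    for _ in range(n_gaps):
        i = int(rng.integers(0, len(df)))
        coord = ("X", "Y", "Z")[int(rng.integers(0, 3))]
        df.loc[i, coord] = np.nan
        gaps.append((df.loc[i, "embryo"], df.loc[i, "cell"], coord, int(i)))

    truth = TrajectoryTruth(cells=cells, true_shifts=list(true_shifts),
                            dt=list(dt), dt_ref=dt_ref, noise_sd=noise_sd,
                            outliers=outliers, gaps=gaps)
    return TrajectoryTable(data=df), truth
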