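"""Automated seam-cell-nucleus detection and candidate-lattice construction.

Seam nuclei are near-uniform bright blobs, so detection is single-scale:
local maxima of a (negated, scale-normalized) Laplacian-of-Gaussian response
at the expected nucleus radius, thresholded relative to the global maximum
response, with near-duplicates merged.  Detections are then paired
left/right and ordered nose→tail; because contralateral partners are not
always each other's nearest neighbours (pair widths in an embryo can exceed
the along-body spacing), several pairing hypotheses are generated — plain
nearest-unused greedy matching seeded from the strongest detections, plus
width-hypothesis greedy matching in which a partner is the unused detection
whose distance best matches a seed-derived pair-width guess.  All candidate
lattices are scored and the five best are returned, mirroring the
select-from-five workflow the plugin's users see; when automation fails a
clear error advises building the lattice manually.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .io import Lattice, Volume

__all__ = [
    "Detection",
    "CandidateLattice",
    "DetectionError",
    "detect_nuclei",
    "pair_detections",
    "score_lattice",
]

MAX_CANDIDATES = 5
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 0.0)


class DetectionError(RuntimeError):
    """Automated lattice building failed; build the lattice manually."""


@dataclass
class Detection:
    center: np.ndarray          # (3,) world µm, (x, y, z)
    radius_est: float           # µm
    intensity: float            # response strength at the maximum


@dataclass
class CandidateLattice:
    lattice: Lattice
    score: float                # lower = better
    score_terms: tuple[float, float, float, float]
    # (pair_width_dispersion, spacing_dispersion, bend_penalty, length_penalty)


def detect_nuclei(v: Volume, expected_radius: float,
                  threshold_rel: float = 0.4) -> list[Detection]:
    """Detect blob-like nuclei of a known radius in a volume.

    Local maxima of the negated LoG response at scale
    ``sigma = expected_radius / sqrt(3)`` exceeding
    ``threshold_rel × max response`` are reported; maxima closer than
    ``expected_radius`` are merged keeping the stronger.
    """
    if expected_radius <= 0:
        raise ValueError("expected_radius must be > 0")
    if not (0 < threshold_rel <= 1):
        raise ValueError("threshold_rel must be in (0, 1]")
    img = v.intensities.astype(np.float32)
    if img.size == 0 or not np.any(img > 0):
        return []
    sigma_vox = expected_radius / np.sqrt(3.0) / v.voxel_size
    resp = -gaussian_laplace(img, sigma=sigma_vox) * sigma_vox ** 2
    vmax = float(resp.max())
    if vmax <= 0:
        return []
    peaks = peak_local_max(resp, min_distance=1,
                           threshold_abs=threshold_rel * vmax)
    if len(peaks) == 0:
        return []
    strengths = resp[tuple(peaks.T)]
    order = np.argsort(strengths)[::-1]
    centers_um = peaks[:, ::-1].astype(float) * v.voxel_size   # (z,y,x)->(x,y,z)

    kept: list[int] = []
    tree_pts: list[np.ndarray] = []
    for i in order:                       # merge duplicates, keep stronger
        p = centers_um[i]
        if all(np.linalg.norm(p - q) >= expected_radius for q in tree_pts):
            kept.append(int(i))
            tree_pts.append(p)
    return [Detection(center=centers_um[i], radius_est=expected_radius,
                      intensity=float(strengths[i])) for i in kept]


# --------------------------------------------------------------------------- #
# scoring
# --------------------------------------------------------------------------- #

def _cv(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m <= 1e-12:
        return 0.0
    return float(np.std(x, ddof=0) / m)


def score_lattice(l: Lattice, weights=DEFAULT_WEIGHTS,
                  expected_length: float | None = None,
                  ) -> tuple[float, tuple[float, float, float, float]]:
    """Score a candidate lattice (lower is better).

    Terms: coefficient of variation of pair widths; CV of consecutive
    midpoint spacings; bend penalty (summed deviation of the midpoint
    polyline's vertex angles from π, i.e. total absolute turning); and a
    relative length penalty against ``expected_length`` if given.  The
    dispersion terms are scale-free.  The final score is the weighted sum.
    """
    mids = l.midpoints
    width_cv = _cv(l.widths)
    seg = np.diff(mids, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    spacing_cv = _cv(seg_len)
    bend = 0.0
    for i in range(1, len(mids) - 1):
        v1 = mids[i - 1] - mids[i]
        v2 = mids[i + 1] - mids[i]
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-300)
        bend += np.pi - float(np.arccos(np.clip(c, -1.0, 1.0)))
    length_pen = 0.0
    if expected_length is not None and expected_length > 0:
        length_pen = abs(float(seg_len.sum()) - expected_length) / expected_length
    terms = (width_cv, spacing_cv, bend, length_pen)
    score = float(np.dot(weights, terms))
    return score, terms


# --------------------------------------------------------------------------- #
# pairing
# --------------------------------------------------------------------------- #

def _greedy_nearest(points: np.ndarray, order: np.ndarray) -> list[tuple[int, int]]:
    """Plain greedy: walk detections in `order`, partner = nearest unused."""
    unused = set(range(len(points)))
    pairs = []
    for i in order:
        if i not in unused:
            continue
        unused.discard(int(i))
        if not unused:
            break
        rest = np.array(sorted(unused))
        j = rest[np.argmin(np.linalg.norm(points[rest] - points[i], axis=1))]
        unused.discard(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def _greedy_width(points: np.ndarray, order: np.ndarray,
                  width: float) -> list[tuple[int, int]]:
    """Greedy with a pair-width hypothesis: partner minimizes |dist − width|."""
    unused = set(range(len(points)))
    pairs = []
    for i in order:
        if i not in unused:
            continue
        unused.discard(int(i))
        if not unused:
            break
        rest = np.array(sorted(unused))
        d = np.linalg.norm(points[rest] - points[i], axis=1)
        j = rest[np.argmin(np.abs(d - width))]
        unused.discard(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def _chain_midpoints(mids: np.ndarray) -> list[int]:
    """Order pair midpoints by nearest-neighbour walking from one extreme end."""
    n = len(mids)
    d2 = np.sum((mids[:, None, :] - mids[None, :, :]) ** 2, axis=2)
    start = int(np.unravel_index(np.argmax(d2), d2.shape)[0])  # end of the diameter
    order = [start]
    unvisited = set(range(n)) - {start}
    while unvisited:
        cur = order[-1]
        rest = np.array(sorted(unvisited))
        nxt = rest[np.argmin(d2[cur, rest])]
        order.append(int(nxt))
        unvisited.discard(int(nxt))
    return order


def _orient_pairs(points: np.ndarray, pairs: list[tuple[int, int]]):
    """Make left/right assignment consistent along the ordered chain.

    The first pair's assignment is arbitrary; each subsequent pair is
    flipped if needed so its left→right direction does not reverse abruptly
    relative to the previous pair (allows gradual helical twist).
    """
    out = [pairs[0]]
    for (i, j) in pairs[1:]:
        prev = points[out[-1][1]] - points[out[-1][0]]
        cur = points[j] - points[i]
        out.append((i, j) if np.dot(prev, cur) >= 0 else (j, i))
    return out


def _ordered_lattice(pts: np.ndarray, pairs: list[tuple[int, int]],
                     weights=DEFAULT_WEIGHTS, expected_length=None):
    """Chain pairs into a lattice (one orientation) and score it."""
    mids = 0.5 * (pts[[i for i, _ in pairs]] + pts[[j for _, j in pairs]])
    chain = _chain_midpoints(mids)
    ordered = [pairs[k] for k in chain]
    consistent = _orient_pairs(pts, ordered)
    left = pts[[i for i, _ in consistent]]
    right = pts[[j for _, j in consistent]]
    try:
        lat = Lattice(left, right)
    except Exception:
        return None, np.inf, (np.inf,) * 4, ordered
    score, terms = score_lattice(lat, weights, expected_length)
    return lat, score, terms, ordered


def _local_search(pts: np.ndarray, pairs: list[tuple[int, int]],
                  weights, expected_length, max_sweeps: int = 30):
    """Improve a pairing by score-guided partner swaps (2-opt) and, when
    spare detections exist, by substituting unused detections into pairs."""

    def cost(pr):
        return _ordered_lattice(pts, pr, weights, expected_length)[1]

    pairs = [tuple(p) for p in pairs]
    best = cost(pairs)
    n_det = len(pts)
    for _ in range(max_sweeps):
        improved = False
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                i1, j1 = pairs[a]
                i2, j2 = pairs[b]
                for alt in (((i1, i2), (j1, j2)), ((i1, j2), (j1, i2))):
                    trial = list(pairs)
                    trial[a], trial[b] = alt
                    s = cost(trial)
                    if s < best - 1e-12:
                        pairs, best, improved = trial, s, True
        used = {k for p in pairs for k in p}
        unused = [k for k in range(n_det) if k not in used]
        if unused:
            for a in range(len(pairs)):
                for slot in (0, 1):
                    for u in unused:
                        trial = list(pairs)
                        pair = list(trial[a])
                        pair[slot] = u
                        trial[a] = tuple(pair)
                        s = cost(trial)
                        if s < best - 1e-12:
                            pairs, best, improved = trial, s, True
                            used = {k for p in pairs for k in p}
                            unused = [k for k in range(n_det) if k not in used]
                            break
        if not improved:
            break
    return pairs, best


def pair_detections(dets: list[Detection], n_pairs: int,
                    nose_hint=None, weights=DEFAULT_WEIGHTS,
                    expected_length: float | None = None,
                    n_seeds: int = 5, n_random_starts: int = 5,
                    seed: int = 0) -> list[CandidateLattice]:
    """Pair detections into up to five ranked candidate lattices.

    Initial pairings come from greedy matching seeded at each of the
    ``n_seeds`` strongest detections (nearest-unused, and nearest to a
    width hypothesis taken from the seed's neighbour distances) plus a few
    seeded random pairings.  Each start is refined by score-guided local
    search — swapping partners between pairs and substituting unused
    detections — then chained nose→tail by walking midpoint proximity.
    Candidates are deduplicated and the five lowest-scoring returned.
    Orientation is resolved by ``nose_hint`` when given; otherwise both
    orientations are emitted as separate candidates.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if len(dets) < 2 * n_pairs:
        raise DetectionError(
            f"only {len(dets)} detections for {n_pairs} pairs — automated "
            "lattice building failed; build the lattice manually")
    pts = np.array([d.center for d in dets])
    strength = np.array([d.intensity for d in dets])
    by_strength = np.argsort(strength)[::-1]
    tree = cKDTree(pts)
    rng = np.random.default_rng(seed)

    starts: list[list[tuple[int, int]]] = [_greedy_nearest(pts, by_strength)]
    for sd in by_strength[:n_seeds]:
        order = np.argsort(np.linalg.norm(pts - pts[sd], axis=1))
        starts.append(_greedy_nearest(pts, order))
        dists, _ = tree.query(pts[sd], k=min(4, len(pts)))
        for w in np.atleast_1d(dists)[1:]:
            starts.append(_greedy_width(pts, order, float(w)))
    for _ in range(n_random_starts):
        perm = rng.permutation(len(pts))
        starts.append([(int(perm[2 * i]), int(perm[2 * i + 1]))
                       for i in range(len(pts) // 2)])

    refined: dict[frozenset, list[tuple[int, int]]] = {}
    for st in starts:
        if len(st) < n_pairs:
            continue
        st = sorted(st, key=lambda ij: strength[ij[0]] + strength[ij[1]],
                    reverse=True)[:n_pairs]
        pr, _ = _local_search(pts, st, weights, expected_length)
        refined[frozenset(frozenset(p) for p in pr)] = pr

    candidates: dict[bytes, CandidateLattice] = {}
    for pr in refined.values():
        lat, score, terms, ordered = _ordered_lattice(pts, pr, weights,
                                                      expected_length)
        if lat is None:
            continue
        variants = [ordered, ordered[::-1]]
        if nose_hint is not None:
            nh = np.asarray(nose_hint, dtype=float)
            m0 = 0.5 * (pts[ordered[0][0]] + pts[ordered[0][1]])
            m1 = 0.5 * (pts[ordered[-1][0]] + pts[ordered[-1][1]])
            variants = [ordered if (np.linalg.norm(m0 - nh)
                                    <= np.linalg.norm(m1 - nh))
                        else ordered[::-1]]
        for var in variants:
            consistent = _orient_pairs(pts, var)
            left = pts[[i for i, _ in consistent]]
            right = pts[[j for _, j in consistent]]
            try:
                lat_v = Lattice(left, right)
            except Exception:
                continue
            sc, tm = score_lattice(lat_v, weights, expected_length)
            key = np.round(np.concatenate([left, right]), 6).tobytes()
            cand = CandidateLattice(lattice=lat_v, score=sc, score_terms=tm)
            if key not in candidates or sc < candidates[key].score:
                candidates[key] = cand
    if not candidates:
        raise DetectionError("no valid candidate lattice could be formed; "
                             "build the lattice manually")
    ranked = sorted(candidates.values(), key=lambda c: c.score)
    return ranked[:MAX_CANDIDATES]
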