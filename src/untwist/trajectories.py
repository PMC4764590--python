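"""Composite-embryo trajectory pipeline: clean, fit, shift, average, re-fit.

Embryos develop on identical programs but start at different times, so axial
(Z) seam-cell trajectories from different embryos are the same sigmoid
shifted in time.  Each cell's Z series is fitted with a three-parameter
logistic ``Z = A / (1 + exp(-B (t - C)))``; embryos are registered by
shifting an integral number of reference timepoints so the inflection
points C agree; the shifted X, Y, Z series are averaged across embryos and
the averages re-fitted with per-cell-type function families to give a
noise-free "average embryo" model.

Goodness of fit is reported as SSR together with the Gaussian-residual
information criteria ``AIC = n·ln(SSR/n) + 2k`` and
``SC = n·ln(SSR/n) + k·ln(n)`` (k = number of parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import ConfigurationError, TrajectoryTable

__all__ = [
    "FitResult",
    "CompositeModel",
    "AlignmentResult",
    "MODEL_FAMILIES",
    "clean_trajectory",
    "fit_growth",
    "select_model",
    "compute_shift",
    "align_and_average",
    "fit_composite",
    "smooth50",
    "neighbor_differences",
    "CELL_TYPE_FITS",
]


# --------------------------------------------------------------------------- #
# model families
# --------------------------------------------------------------------------- #

def _logistic3(t, A, B, C):
    return A / (1.0 + np.exp(-np.clip(B * (t - C), -500, 500)))


def _gompertz3(t, A, B, C):
    return A * np.exp(-np.exp(-np.clip(B * (t - C), -500, 500)))


def _von_bertalanffy(t, A, B, C):
    return A * (1.0 - np.exp(-np.clip(B * (t - C), -500, 500)))


def _exponential3(t, A, B, C):
    return A - (A - B) * np.exp(-np.clip(C * t, -500, 500))


def _mmf4(t, A, B, C, D):
    return A - (A - B) / (1.0 + np.power(np.abs(C * t) + 1e-12, D))


def _logistic4(t, A, B, C, D):
    return B + (A - B) / (1.0 + np.exp(np.clip((C - t) / D, -500, 500)))


def _power(t, a, b, c):
    return a * np.power(np.maximum(t, 1e-9), b) + c


def _guess_sigmoid(t, y):
    A = float(np.max(y))
    half = 0.5 * A
    above = np.nonzero(y >= half)[0]
    C = float(t[above[0]]) if len(above) else float(np.median(t))
    dy = np.gradient(y, t)
    slope = float(np.max(np.abs(dy))) if np.any(dy) else 1.0
    B = max(4.0 * slope / A, 1e-4) if A > 0 else 0.05
    return A, B, C


#: family name -> (function, parameter names, initial-guess builder)
MODEL_FAMILIES: dict[str, tuple] = {
    "logistic3": (_logistic3, ("A", "B", "C"),
                  lambda t, y: _guess_sigmoid(t, y)),
    "gompertz3": (_gompertz3, ("A", "B", "C"),
                  lambda t, y: _guess_sigmoid(t, y)),
    "vonBertalanffy": (_von_bertalanffy, ("A", "B", "C"),
                       lambda t, y: (np.max(y),
                                     _guess_sigmoid(t, y)[1] / 4.0,
                                     t[0] - 1.0)),
    "exponential3": (_exponential3, ("A", "B", "C"),
                     lambda t, y: (np.max(y), y[0],
                                   3.0 / max(t[-1] - t[0], 1e-6))),
    "mmf4": (_mmf4, ("A", "B", "C", "D"),
             lambda t, y: (np.max(y), y[0],
                           1.0 / max(_guess_sigmoid(t, y)[2], 1e-6), 2.0)),
    "logistic4": (_logistic4, ("A", "B", "C", "D"),
                  lambda t, y: (np.max(y), np.min(y), _guess_sigmoid(t, y)[2],
                                max((t[-1] - t[0]) / 10.0, 1e-6))),
    "power": (_power, ("a", "b", "c"),
              lambda t, y: ((y[-1] - y[0]) / max(t[-1] - t[0], 1e-6), 1.0, y[0])),
}

_POLY_FAMILIES = {"linear": 1, "poly4": 4}
_ALL_KINDS = (list(MODEL_FAMILIES) + list(_POLY_FAMILIES) + ["smooth50"])


@dataclass
class FitResult:
    model_kind: str
    params: dict[str, float]
    ssr: float
    aic: float
    sc: float
    n: int
    converged: bool = True
    fitted: np.ndarray | None = field(default=None, repr=False)
    t: np.ndarray | None = field(default=None, repr=False)
    message: str = ""

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model_kind in MODEL_FAMILIES:
            f, names, _ = MODEL_FAMILIES[self.model_kind]
            return f(t, *[self.params[p] for p in names])
        if self.model_kind == "linear":
            return self.params["p1"] * t + self.params["p2"]
        if self.model_kind == "poly4":
            return np.polyval([self.params[f"p{i}"] for i in range(4, -1, -1)], t)
        if self.model_kind == "smooth50":
            # nonparametric: interpolate the smoothed series
            return np.interp(t, self.t, self.fitted)
        raise ValueError(f"unknown model kind {self.model_kind!r}")


def _criteria(ssr: float, n: int, k: int) -> tuple[float, float]:
    ssr_f = max(ssr, 1e-30)
    base = n * np.log(ssr_f / n)
    return float(base + 2 * k), float(base + k * np.log(n))


def fit_growth(tr, t, model_kind: str) -> FitResult:
    """Fit one coordinate series with the named growth/trend family.

    Nonlinear families are fitted by least squares from data-driven initial
    guesses (e.g. for the logistic: A = max value, C = time at half-max,
    B = 4·max slope / A).  Non-convergence is reported in the result's
    ``converged`` flag rather than raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(tr, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    n = len(y)
    if model_kind not in _ALL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; "
                         f"choose from {_ALL_KINDS}")

    if model_kind == "smooth50":
        fitted = smooth50(y)
        ssr = float(np.sum((y - fitted) ** 2))
        aic, sc = _criteria(ssr, n, 2)
        return FitResult("smooth50", {}, ssr, aic, sc, n, True, fitted, t)

    if model_kind in _POLY_FAMILIES:
        deg = _POLY_FAMILIES[model_kind]
        if n < deg + 1:
            return FitResult(model_kind, {}, np.inf, np.inf, np.inf, n, False,
                             message="too few points")
        coef = np.polyfit(t, y, deg)
        fitted = np.polyval(coef, t)
        ssr = float(np.sum((y - fitted) ** 2))
        k = deg + 1
        aic, sc = _criteria(ssr, n, k)
        if model_kind == "linear":      # slope p1, intercept p2
            params = {"p1": float(coef[0]), "p2": float(coef[1])}
        else:
            params = {f"p{deg - i}": float(c) for i, c in enumerate(coef)}
        return FitResult(model_kind, params, ssr, aic, sc, n, True, fitted, t)

    f, names, guess = MODEL_FAMILIES[model_kind]
    k = len(names)
    if n < k + 1:
        return FitResult(model_kind, {}, np.inf, np.inf, np.inf, n, False,
                         message="too few points")
    p0 = np.asarray(guess(t, y), dtype=float)
    try:
        popt, _ = curve_fit(f, t, y, p0=p0, maxfev=20000)
        fitted = f(t, *popt)
        if not np.all(np.isfinite(fitted)):
            raise RuntimeError("non-finite prediction")
        converged, msg = True, ""
    except Exception as exc:  # flagged, not raised
        popt, fitted = p0, f(t, *p0)
        converged, msg = False, str(exc)
    ssr = float(np.sum((y - fitted) ** 2))
    aic, sc = _criteria(ssr, n, k)
    return FitResult(model_kind, dict(zip(names, map(float, popt))),
                     ssr, aic, sc, n, converged, np.asarray(fitted), t, msg)


def select_model(tr, t, candidates: list[str]) -> list[FitResult]:
    """Fit every candidate family and rank ascending by AIC.

    Non-converged fits sort last regardless of their nominal AIC; SSR and
    SC are carried on each result for inspection.
    """
    if len(candidates) < 1:
        raise ValueError("at least one candidate family is required")
    fits = [fit_growth(tr, t, kind) for kind in candidates]
    return sorted(fits, key=lambda r: (not r.converged,
                                       r.aic if np.isfinite(r.aic) else np.inf))


# --------------------------------------------------------------------------- #
# cleaning
# --------------------------------------------------------------------------- #

def clean_trajectory(tr, outlier_z: float = 6.0,
                     manual_marks: list[int] | None = None) -> np.ndarray:
    """Replace outliers and gaps in one coordinate series.

    Indices in ``manual_marks``, indices whose residual from the 5-point
    rolling median exceeds ``outlier_z`` × the MAD of all residuals, and all
    missing (NaN) values are replaced by linear interpolation between the
    nearest valid neighbours; runs at either end are filled by
    nearest-valid extension.  A clean series passes through unchanged.
    """
    y = np.asarray(tr, dtype=float).copy()
    if len(y) < 3:
        raise ValueError("series must have length >= 3")
    bad = ~np.isfinite(y)
    if bad.all():
        raise ValueError("all values are missing")
    if manual_marks:
        bad[np.asarray(manual_marks, dtype=int)] = True

    # full 5-point windows only: truncated edge windows bias the median and
    # would spuriously flag smooth boundary points
    med = pd.Series(y).rolling(5, center=True, min_periods=5).median().to_numpy()
    resid = y - med
    valid = np.isfinite(resid) & ~bad
    if valid.any():
        # robust residual scale; on very smooth series the MAD collapses to
        # zero (the rolling median reproduces the data exactly), so fall
        # back to an upper-percentile scale before giving up
        scale = float(np.median(np.abs(resid[valid])))
        if scale <= 1e-12:
            scale = float(np.percentile(np.abs(resid[valid]), 90))
        if scale > 1e-12:
            bad |= np.isfinite(resid) & (np.abs(resid) > outlier_z * scale)
    if bad.all():
        raise ValueError("no valid values remain after flagging")

    idx = np.arange(len(y))
    y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])   # endpoint runs extend
    return y


# --------------------------------------------------------------------------- #
# temporal registration and averaging
# --------------------------------------------------------------------------- #

def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def compute_shift(fit_ref: FitResult, fit_other: FitResult,
                  dt_ref: float = 1.0) -> int:
    """Integer timepoint shift aligning two logistic inflection points.

    ``shift = round((C_ref − C_other) / dt_ref)`` in reference-grid
    timepoints, rounding half away from zero; e.g. inflection points 42.6
    and 37.7 (already in timepoint units, ``dt_ref = 1``) give a shift of 5.
    """
    for fit in (fit_ref, fit_other):
        if "C" not in fit.params:
            raise ValueError(
                f"fit of kind {fit.model_kind!r} has no inflection parameter C")
    return _round_half_away((fit_ref.params["C"] - fit_other.params["C"]) / dt_ref)


@dataclass
class AlignmentResult:
    aligned: TrajectoryTable
    averaged: pd.DataFrame        # cell, time_min, X, Y, Z, sd_X, sd_Y, sd_Z, n
    shifts: dict[tuple, int]      # (embryo, cell) -> applied shift (ref timepoints)
    dt_ref: float
    reference_embryo: object


def align_and_average(tset: TrajectoryTable, reference_embryo,
                      clean: bool = True, outlier_z: float = 6.0) -> AlignmentResult:
    """Temporally register embryos to a reference and average their trajectories.

    For every cell of every embryo the (cleaned) Z series is fitted with the
    three-parameter logistic; the embryo's series are shifted by the integer
    number of reference timepoints that aligns the inflection point C with
    the reference embryo's fit for the same cell.  The Z-derived shift is
    applied identically to X, Y and Z.  Embryos on coarser grids are
    resampled to the reference grid (the finest dt present) by linear
    interpolation before averaging; averages ignore missing values and the
    per-timepoint sample SD is retained.

    Cells absent from the reference embryo are shifted by the embryo's
    median shift.
    """
    embryos = tset.embryos
    if reference_embryo not in embryos:
        raise ValueError(f"reference embryo {reference_embryo!r} not in table")
    dt_ref = min(tset.dt(e) for e in embryos)

    # per (embryo, cell) logistic fit of the axial coordinate
    fits: dict[tuple, FitResult] = {}
    for e in embryos:
        for cell in sorted(tset.data.loc[tset.data["embryo"] == e, "cell"].unique()):
            ser = tset.series(e, cell)
            z = ser["Z"].to_numpy(float)
            if clean:
                z = clean_trajectory(z, outlier_z=outlier_z)
            fits[(e, cell)] = fit_growth(z, ser["time_min"].to_numpy(float),
                                         "logistic3")

    shifts: dict[tuple, int] = {}
    for e in embryos:
        cells_e = [c for (ee, c) in fits if ee == e]
        known = []
        for cell in cells_e:
            if (reference_embryo, cell) in fits:
                sh = compute_shift(fits[(reference_embryo, cell)],
                                   fits[(e, cell)], dt_ref)
                shifts[(e, cell)] = sh
                known.append(sh)
        fallback = int(np.median(known)) if known else 0
        for cell in cells_e:
            if (e, cell) not in shifts:
                shifts[(e, cell)] = fallback    # cell absent from reference

    # common reference grid covering all shifted series
    t_min, t_max = np.inf, -np.inf
    for e in embryos:
        sub = tset.data[tset.data["embryo"] == e]
        for cell in sub["cell"].unique():
            ts = sub.loc[sub["cell"] == cell, "time_min"].to_numpy(float)
            off = shifts[(e, cell)] * dt_ref
            t_min = min(t_min, ts.min() + off)
            t_max = max(t_max, ts.max() + off)
    grid = np.arange(0.0, t_max - t_min + dt_ref / 2, dt_ref) + t_min

    rows = []
    for e in embryos:
        sub = tset.data[tset.data["embryo"] == e]
        for cell in sorted(sub["cell"].unique()):
            ser = tset.series(e, cell)
            ts = ser["time_min"].to_numpy(float) + shifts[(e, cell)] * dt_ref
            rec = {"embryo": e, "cell": cell, "time_min": grid}
            for coord in ("X", "Y", "Z"):
                v = ser[coord].to_numpy(float)
                if clean:
                    v = clean_trajectory(v, outlier_z=outlier_z)
                vi = np.interp(grid, ts, v, left=np.nan, right=np.nan)
                rec[coord] = vi
            rows.append(pd.DataFrame(rec))
    aligned = TrajectoryTable(data=pd.concat(rows, ignore_index=True))

    avg_rows = []
    for cell, grp in aligned.data.groupby("cell"):
        rec = {"cell": cell, "time_min": grid}
        for coord in ("X", "Y", "Z"):
            wide = grp.pivot_table(index="time_min", columns="embryo",
                                   values=coord, dropna=False).reindex(grid)
            rec[coord] = wide.mean(axis=1, skipna=True).to_numpy()
            rec[f"sd_{coord}"] = wide.std(axis=1, ddof=1, skipna=True).to_numpy()
        rec["n"] = grp.pivot_table(index="time_min", columns="embryo",
                                   values="Z", dropna=False).reindex(grid) \
                      .notna().sum(axis=1).to_numpy()
        avg_rows.append(pd.DataFrame(rec))
    averaged = pd.concat(avg_rows, ignore_index=True)

    return AlignmentResult(aligned=aligned, averaged=averaged, shifts=shifts,
                           dt_ref=dt_ref, reference_embryo=reference_embryo)


# --------------------------------------------------------------------------- #
# composite-model fitting
# --------------------------------------------------------------------------- #

#: per-cell-type fitting family map for (X, Y, Z)
CELL_TYPE_FITS: dict[str, tuple[str, str, str]] = {
    "seam": ("power", "linear", "logistic3"),
    "CAN": ("smooth50", "smooth50", "logistic3"),
    "AIY": ("poly4", "linear", "logistic3"),
    "ALA": ("linear", "linear", "logistic3"),
}


def _cell_type(name: str) -> str:
    from .synthetic import SEAM_PAIR_ORDER
    if name.upper().startswith("CAN"):
        return "CAN"
    if name.upper().startswith("AIY"):
        return "AIY"
    if name.upper().startswith("ALA") or name.upper().startswith("AX") \
            or name in ("Q", "Q/V5"):
        return "ALA" if not name.startswith("Q") else "seam"
    for seam in SEAM_PAIR_ORDER:
        if name.startswith(seam):
            return "seam"
    raise ConfigurationError(
        f"no fitting family configured for cell {name!r}; the map is "
        f"{CELL_TYPE_FITS}")


@dataclass
class CompositeModel:
    """Average-embryo model: fitted X/Y/Z per cell on the reference grid."""

    grid: np.ndarray
    fits: dict[str, dict[str, FitResult]]          # cell -> coord -> fit
    fitted: pd.DataFrame                           # cell, time_min, Xfit, Yfit, Zfit
    residual_stats: pd.DataFrame                   # cell, coord, mu_avg_fit, sigma_avg_fit
    shifts: dict[tuple, int] = field(default_factory=dict)


def fit_composite(averaged: pd.DataFrame,
                  shifts: dict[tuple, int] | None = None) -> CompositeModel:
    """Fit averaged per-cell series with the per-cell-type family map.

    Seam cells get power/linear/logistic3 (X/Y/Z), CAN cells 50-point
    smoothing for X and Y, AIY cells a 4th-degree polynomial X, and ALA and
    its neurite points linear X/Y — all with logistic3 axial fits.  For each
    coordinate the mean and SD of |averaged − fitted| over time are recorded.
    """
    grid = np.unique(averaged["time_min"].to_numpy(float))
    fits: dict[str, dict[str, FitResult]] = {}
    fitted_rows, stat_rows = [], []
    for cell, grp in averaged.groupby("cell"):
        fam = CELL_TYPE_FITS[_cell_type(str(cell))]
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(float)
        fits[cell] = {}
        rec = {"cell": cell, "time_min": t}
        for coord, kind in zip(("X", "Y", "Z"), fam):
            y = grp[coord].to_numpy(float)
            ok = np.isfinite(y)
            fr = fit_growth(y[ok], t[ok], kind)
            fits[cell][coord] = fr
            pred = np.full_like(y, np.nan)
            pred[ok] = fr.predict(t[ok]) if kind != "smooth50" else fr.fitted
            rec[f"{coord}fit"] = pred
            absdiff = np.abs(y[ok] - pred[ok])
            stat_rows.append({"cell": cell, "coord": coord, "model": kind,
                              "mu_avg_fit": float(np.mean(absdiff)),
                              "sigma_avg_fit": float(np.std(absdiff, ddof=1))
                              if len(absdiff) > 1 else 0.0})
        fitted_rows.append(pd.DataFrame(rec))
    return CompositeModel(grid=grid, fits=fits,
                          fitted=pd.concat(fitted_rows, ignore_index=True),
                          residual_stats=pd.DataFrame(stat_rows),
                          shifts=shifts or {})


def smooth50(series, span: int = 50) -> np.ndarray:
    """Local linear smoothing over a centered span (default 50 samples).

    Each output point is the value at the window center of a
    tricube-weighted linear least-squares fit over the span; windows are
    truncated at the boundaries.  Straight-line input is reproduced exactly.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("series must have length >= 2")
    span = min(span, n)
    half = span // 2
    out = np.empty(n)
    x = np.arange(n, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xs, ys = x[lo:hi], y[lo:hi]
        d = np.abs(xs - i)
        dmax = d.max() if d.max() > 0 else 1.0
        w = (1 - (d / (dmax + 1.0)) ** 3) ** 3          # tricube, strictly > 0
        W = np.sqrt(w)
        A = np.stack([xs - i, np.ones_like(xs)], axis=1)
        coef, *_ = np.linalg.lstsq(A * W[:, None], ys * W, rcond=None)
        out[i] = coef[1]
    return out


def neighbor_differences(model: CompositeModel,
                         order: list[str] | None = None) -> pd.DataFrame:
    """Axial separations between adjacent seam-cell pairs over time.

    Computes, at every timepoint of the composite grid, the difference of
    fitted Z between consecutive pairs in anterior→posterior order
    (including origin→H0, the origin sitting at Z = 0), plus each pair's
    start-to-end change.  Uniform elongation scales all separations by the
    same factor.
    """
    from .synthetic import SEAM_PAIR_ORDER
    if order is None:
        order = SEAM_PAIR_ORDER
    present = set(model.fits)
    missing = [c for c in order if c not in present]
    if missing:
        raise ValueError(f"composite model is missing seam cells {missing}")

    t = model.grid
    z = {"origin": np.zeros_like(t)}
    for c in order:
        z[c] = model.fits[c]["Z"].predict(t)
    chain = ["origin"] + list(order)
    rows = []
    for a, b in zip(chain[:-1], chain[1:]):
        sep = z[b] - z[a]
        change = float(sep[-1] - sep[0]) if len(sep) > 1 else np.nan
        for ti, si in zip(t, sep):
            rows.append({"pair": f"{a}-{b}", "time_min": ti, "separation": si,
                         "start_to_end_change": change})
    return pd.DataFrame(rows)
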