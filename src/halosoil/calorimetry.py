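"""Growth-kinetic feature extraction from isothermal microcalorimetry curves.

An ampoule of soil in an isothermal calorimeter yields a power-time curve:
heat flow P(t) in μW per g soil. Without substrate the curve is flat and its
mean is the basal heat release P_bas. After glucose amendment the curve
follows a microbial growth curve (lag, exponential, stationary, decline);
its early, substrate-unlimited portion obeys

    P(t) = A + B·exp(k·t)

where A (μW/g) is heat flow uncoupled from growth, B (μW/g) the initial
heat flow of the growing fraction, and k (1/h) the specific growth rate of
the soil microbial community. The fitter below estimates (A, B, k) by
separable least squares: for each candidate k the conditionally linear
(A, B) are solved in closed form, the best grid candidate is refined by
golden-section search. This is deterministic and globally robust, with no
starting-value sensitivity.

Peak descriptors P_max (maximum smoothed heat flow) and T_max (its time)
are read off a centred moving-average smoothing of the curve. Internal
units are hours and μW/g; T_max is additionally reported in minutes in the
batch table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from halosoil.exceptions import FitError, InputError

_K_BOUNDS = (1e-3, 10.0)  # 1/h; grid span for the growth-rate search
_N_GRID = 400
_REL_TOL = 1e-6
# exp() overflow guard: candidates with k * t_max beyond this are infeasible
# (sums of e^{2kt} must stay inside float range)
_MAX_EXPONENT = 340.0


@dataclass
class PowerTimeCurve:
    """A heat-flow time series for one ampoule.

    ``t`` in hours (strictly increasing), ``p`` in μW per g soil,
    ``mode`` either ``"basal"`` or ``"substrate_induced"``.
    """

    t: np.ndarray
    p: np.ndarray
    sample_id: str = ""
    mode: str = "substrate_induced"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.ndim != 1 or self.p.ndim != 1 or len(self.t) != len(self.p):
            raise InputError("t and p must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise InputError("a power-time curve needs at least 3 points")
        if not np.all(np.diff(self.t) > 0):
            raise InputError("time axis must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.p))):
            raise InputError("times and heat flows must be finite")
        if self.mode not in ("basal", "substrate_induced"):
            raise InputError(f"unknown curve mode {self.mode!r}")


@dataclass
class CurveFeatures:
    """Peak descriptors of a substrate-induced curve."""

    p_max: float  # μW/g, maximum of the smoothed curve
    t_max: float  # hours, time of that maximum (earliest on ties)
    smoothing_width: int
    p_bas: float | None = None


@dataclass
class GrowthFit:
    """Fitted parameters of P = A + B·exp(k·t) on the early-growth window."""

    a: float
    b: float
    k: float
    window: tuple[float, float]
    rss: float
    r2: float
    lag: float  # hours; ln(A/B)/k when B < A, else 0


def moving_average(p: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if width < 1 or width % 2 == 0:
        raise InputError(f"smoothing width must be a positive odd integer, got {width}")
    return (
        pd.Series(np.asarray(p, dtype=float))
        .rolling(width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def basal_power(curve: PowerTimeCurve, discard_initial: float = 1.0) -> float:
    """Mean heat flow of a basal curve after an equilibration discard.

    The first ``discard_initial`` hours are dropped to exclude the ampoule
    insertion transient; at least 3 points must remain.
    """
    if curve.mode != "basal":
        raise InputError("basal_power requires a curve in basal mode")
    mask = curve.t > discard_initial
    if mask.sum() < 3:
        raise InputError(
            f"only {int(mask.sum())} points remain after discarding the first "
            f"{discard_initial} h; need at least 3"
        )
    return float(curve.p[mask].mean())


def peak_features(curve: PowerTimeCurve, smoothing_width: int = 5) -> CurveFeatures:
    """P_max and T_max of a substrate-induced curve.

    The curve is smoothed by a centred moving average of ``smoothing_width``
    points; P_max is the maximum of the smoothed series and T_max the time
    of its earliest occurrence.
    """
    if curve.mode != "substrate_induced":
        raise InputError("peak_features requires a substrate-induced curve")
    if smoothing_width >= len(curve.t):
        raise InputError(
            f"smoothing width {smoothing_width} must be smaller than the "
            f"series length {len(curve.t)}"
        )
    sm = moving_average(curve.p, smoothing_width)
    i = int(np.argmax(sm))  # argmax returns the earliest maximum
    return CurveFeatures(
        p_max=float(sm[i]), t_max=float(curve.t[i]), smoothing_width=smoothing_width
    )


def select_window(
    curve: PowerTimeCurve,
    features: CurveFeatures | None = None,
    frac: float = 0.9,
    smoothing_width: int = 5,
) -> tuple[float, float]:
    """Early-growth fitting window [t_lo, t_hi].

    The window runs from the start of the curve to the earliest time at
    which the smoothed heat flow reaches ``frac`` × P_max — a quantitative
    stand-in for the substrate-unlimited initial phase.
    """
    if not 0.0 < frac < 1.0:
        raise InputError(f"frac must be in (0, 1), got {frac}")
    if features is None:
        features = peak_features(curve, smoothing_width)
    sm = moving_average(curve.p, features.smoothing_width)
    above = np.nonzero(sm >= frac * features.p_max)[0]
    i_hi = int(above[0])
    if i_hi == 0:
        raise FitError(
            "degenerate window: the curve already meets frac × P_max at its "
            "first point; lower frac or start recording earlier"
        )
    if i_hi + 1 < 5:
        raise FitError(
            f"window holds only {i_hi + 1} points; need ≥ 5 — use a smaller "
            "frac or denser sampling"
        )
    return float(curve.t[0]), float(curve.t[i_hi])


def _linear_solve(t: np.ndarray, p: np.ndarray, k: float) -> tuple[float, float, float]:
    """Closed-form least squares for (A, B) at fixed k; returns (A, B, RSS).

    Infeasible candidates (overflow, singular design, A < 0 or B ≤ 0)
    return RSS = inf.
    """
    if k * t[-1] > _MAX_EXPONENT:
        return np.nan, np.nan, np.inf
    e = np.exp(k * t)
    n = len(t)
    with np.errstate(over="ignore", invalid="ignore"):
        se, see = e.sum(), (e * e).sum()
        sp, sep = p.sum(), (e * p).sum()
        det = n * see - se * se
    if not np.isfinite(det) or det <= 0:
        return np.nan, np.nan, np.inf
    a = (see * sp - se * sep) / det
    b = (n * sep - se * sp) / det
    # B must be meaningfully positive: a constant curve yields B of order
    # machine epsilon, which is "no growth", not a feasible fit
    b_min = 1e-8 * max(1.0, float(np.max(np.abs(p))))
    if not (np.isfinite(a) and np.isfinite(b)) or a < 0 or b <= b_min:
        return np.nan, np.nan, np.inf
    resid = p - a - b * e
    return a, b, float(resid @ resid)


def fit_growth_model(
    curve: PowerTimeCurve,
    window: tuple[float, float] | None = None,
    frac: float = 0.9,
    smoothing_width: int = 5,
    k_bounds: tuple[float, float] = _K_BOUNDS,
    n_grid: int = _N_GRID,
    rel_tol: float = _REL_TOL,
) -> GrowthFit:
    """Fit P = A + B·exp(k·t) on the early-growth window.

    Separable least squares: k is scanned on a log grid over ``k_bounds``
    (``n_grid`` points); at each k the conditionally linear (A, B) are
    solved in closed form with the constraints A ≥ 0, B > 0 enforced by
    discarding violating candidates. The best grid cell is refined by
    golden-section search on log k to relative tolerance ``rel_tol``.
    """
    if window is None:
        window = select_window(curve, frac=frac, smoothing_width=smoothing_width)
    t_lo, t_hi = window
    mask = (curve.t >= t_lo) & (curve.t <= t_hi)
    if mask.sum() < 5:
        raise FitError(f"window [{t_lo}, {t_hi}] holds {int(mask.sum())} points; need ≥ 5")
    t = curve.t[mask]
    p = curve.p[mask]

    log_k = np.linspace(math.log(k_bounds[0]), math.log(k_bounds[1]), n_grid)
    rss = np.empty(n_grid)
    for i, lk in enumerate(log_k):
        rss[i] = _linear_solve(t, p, math.exp(lk))[2]
    if not np.any(np.isfinite(rss)):
        raise FitError("no exponential growth detected")
    i_best = int(np.argmin(rss))

    # golden-section refinement on log k between the neighbours of the best cell
    lo = log_k[max(i_best - 1, 0)]
    hi = log_k[min(i_best + 1, n_grid - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc = _linear_solve(t, p, math.exp(c))[2]
    fd = _linear_solve(t, p, math.exp(d))[2]
    while (hi - lo) > rel_tol:
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = _linear_solve(t, p, math.exp(c))[2]
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = _linear_solve(t, p, math.exp(d))[2]
    k_hat = math.exp(0.5 * (lo + hi))
    a, b, rss_hat = _linear_solve(t, p, k_hat)
    if not np.isfinite(rss_hat):  # refinement landed infeasible; fall back to grid
        k_hat = math.exp(log_k[i_best])
        a, b, rss_hat = _linear_solve(t, p, k_hat)
    tss = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - rss_hat / tss if tss > 0 else float("-inf")
    lag = math.log(a / b) / k_hat if 0 < b < a else 0.0
    return GrowthFit(a=a, b=b, k=k_hat, window=(t_lo, t_hi), rss=rss_hat, r2=r2, lag=lag)


_BASAL_FEATURES = ["p_bas"]
_INDUCED_FEATURES = ["p_max", "t_max", "a", "b", "k", "lag"]


def batch_report(
    curves: list[PowerTimeCurve],
    group_map: dict[str, str],
    discard_initial: float = 1.0,
    frac: float = 0.9,
    smoothing_width: int = 5,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-sample features and per-group summaries with Tukey letters.

    Basal and substrate-induced curves are reported in separate tables.
    Group summaries carry mean ± sd per feature and compact-letter-display
    significance letters from a one-way ANOVA with Tukey's HSD; letters are
    omitted (with a warning) when any group has fewer than 2 samples.
    ``t_max_min`` restates the peak time in minutes.
    """
    from halosoil.community import anova_tukey  # deferred: avoids import cycle

    basal_rows, induced_rows = [], []
    for c in curves:
        grp = group_map.get(c.sample_id)
        if grp is None:
            raise InputError(f"sample {c.sample_id!r} missing from group_map")
        if c.mode == "basal":
            basal_rows.append(
                {"sample_id": c.sample_id, "group": grp,
                 "p_bas": basal_power(c, discard_initial)}
            )
        else:
            feat = peak_features(c, smoothing_width)
            fit = fit_growth_model(c, frac=frac, smoothing_width=smoothing_width)
            induced_rows.append(
                {"sample_id": c.sample_id, "group": grp, "p_max": feat.p_max,
                 "t_max": feat.t_max, "t_max_min": feat.t_max * 60.0,
                 "a": fit.a, "b": fit.b, "k": fit.k, "lag": fit.lag, "r2": fit.r2}
            )

    out: dict[str, pd.DataFrame] = {}
    for name, rows, feats in (
        ("basal", basal_rows, _BASAL_FEATURES),
        ("induced", induced_rows, _INDUCED_FEATURES),
    ):
        if not rows:
            continue
        df = pd.DataFrame(rows)
        out[name] = df
        sizes = df.groupby("group").size()
        letters_ok = len(sizes) >= 2 and (sizes >= 2).all()
        if not letters_ok and len(sizes) >= 2:
            warnings.warn(
                "a group has fewer than 2 samples; significance letters omitted",
                stacklevel=2,
            )
        summary_rows = []
        for feat in feats:
            grouped = df.groupby("group")[feat]
            means, sds = grouped.mean(), grouped.std()
            if letters_ok:
                _, _, letters = anova_tukey(
                    df[feat].to_numpy(), df["group"].to_numpy(), alpha=alpha
                )
            elif len(sizes) == 1:
                letters = {sizes.index[0]: "a"}
            else:
                letters = {g: "" for g in sizes.index}
            for g in means.index:
                summary_rows.append(
                    {"feature": feat, "group": g, "mean": means[g],
                     "sd": sds[g], "n": int(sizes[g]), "letters": letters[g]}
                )
        out[f"{name}_summary"] = pd.DataFrame(summary_rows)
    return out
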