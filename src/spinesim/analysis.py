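"""Trace statistics and the recursive foci-count area estimator.

Summary statistics
------------------
Mean and SD of the area series, its normalized autocorrelation function,
a bootstrap SD of the temporal mean (50 i.i.d. resamples of time points by
default) and the mean lifetime of completed foci.  Two-sample comparisons
of replicate means use Welch's unequal-variance t-test.

Area estimator
--------------
The spine area can be predicted from the number of active polymerization
foci alone.  The estimator is the linear recursion

    Abar(t_j) = Abar(t_{j-1}) - Phi (Abar(t_{j-1}) - A_s)
                + m n_f(t_j) + b,

i.e. per step the area relaxes toward the resting area A_s at rate Phi and
gains ``m`` per active focus plus a baseline ``b``.  Fitting minimizes the
sum of squared deviations between the recursion and the observed area over
a training window.  Because the recursion is linear in (A0, m, b) for
fixed Phi, the fit profiles those three coefficients out exactly with
linear least squares and optimizes the remaining one-dimensional problem
over Phi in [0, 1] — equivalent to the four-parameter nonlinear
least-squares problem but deterministic and robust.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, signal, stats

from .simulator import SimulationTrace

__all__ = [
    "SummaryStats",
    "EstimatorParams",
    "area_statistics",
    "welch_test",
    "fit_area_estimator",
    "predict_area",
    "delta_area_regression",
    "AreaEstimator",
    "AreaEstimatorResults",
]


@dataclass
class SummaryStats:
    """Summary of an area trace."""

    mean_area: float
    sd_area: float
    acf: np.ndarray
    bootstrap_sd: float
    mean_lifetime: float


@dataclass
class EstimatorParams:
    """Parameters of the recursive area estimator.

    ``m``: area increment per focus per step (μm²); ``b``: baseline
    increment per step (μm²); ``phi``: decay rate toward the resting area
    per step, in [0, 1]; ``a0``: initial estimate Abar(t0) (μm²); ``a_s``:
    resting area (μm²).
    """

    m: float
    b: float
    phi: float
    a0: float
    a_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.a_s <= 0:
            raise ValueError("a_s must be positive")


def area_statistics(
    trace: SimulationTrace,
    n_boot: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> SummaryStats:
    """Temporal mean/SD, ACF, bootstrap SD of the mean, mean focus lifetime.

    The ACF uses biased normalization up to ``min(len/2, 10 min of steps)``
    lags.  The bootstrap resamples individual time points i.i.d. with
    replacement, so it underestimates the uncertainty of autocorrelated
    series; it mirrors the replicate-comparison convention used throughout.
    """
    area = np.asarray(trace.area, dtype=float)
    if len(area) < 2:
        raise ValueError("trace must contain at least 2 records")
    if rng is None:
        rng = np.random.default_rng(0)

    mean = float(area.mean())
    sd = float(area.std(ddof=0))

    if sd == 0.0:
        acf_vals = np.array([1.0])
        boot_sd = 0.0
    else:
        from statsmodels.tsa.stattools import acf as sm_acf

        dt = trace.params.dt if trace.params is not None else 1.0
        nlags = int(min(len(area) // 2, round(600.0 / dt)))
        acf_vals = sm_acf(area, nlags=nlags, adjusted=False, fft=True)
        resamples = rng.integers(0, len(area), size=(n_boot, len(area)))
        boot_sd = float(area[resamples].mean(axis=1).std(ddof=0))

    lifetimes = trace.focus_log["lifetime"].to_numpy()
    mean_lifetime = float(lifetimes.mean()) if len(lifetimes) else float("nan")
    return SummaryStats(mean, sd, acf_vals, boot_sd, mean_lifetime)


def welch_test(sample_a, sample_b) -> Tuple[float, float]:
    """Two-sided Welch unequal-variance t-test.

    Raises ``ValueError`` when both samples have zero variance (the
    statistic is undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("Welch test undefined: both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _recursion_basis(foci: np.ndarray, phi: float, a_s: float):
    """Forward responses of the recursion to each parameter.

    With r = 1 - phi the recursion output decomposes as
    ``Abar = a0 * h_a0 + m * h_m + b * h_b + offset`` where each basis is
    the same linear filter ``y_j = r y_{j-1} + x_j`` applied to a
    parameter-specific input.
    """
    n = len(foci)
    r = 1.0 - phi
    a_coef = [1.0, -r]

    x0 = np.zeros(n)
    x0[0] = 1.0
    h_a0 = signal.lfilter([1.0], a_coef, x0)

    xm = foci.astype(float).copy()
    xm[0] = 0.0
    h_m = signal.lfilter([1.0], a_coef, xm)

    xb = np.ones(n)
    xb[0] = 0.0
    h_b = signal.lfilter([1.0], a_coef, xb)

    offset = phi * a_s * h_b
    return h_a0, h_m, h_b, offset


def predict_area(
    params: EstimatorParams,
    foci_series,
    reference=None,
) -> Tuple[np.ndarray, Optional[float]]:
    """Run the recursion forward over a focus-count series.

    The first output element is ``a0`` (the count at the first index is not
    consumed).  Returns ``(predicted, rmse)`` with ``rmse`` computed against
    *reference* when supplied, else None.
    """
    foci = np.asarray(foci_series, dtype=float)
    if len(foci) == 0:
        raise ValueError("empty foci series")
    h_a0, h_m, h_b, offset = _recursion_basis(foci, params.phi, params.a_s)
    pred = params.a0 * h_a0 + params.m * h_m + params.b * h_b + offset
    rmse = None
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != pred.shape:
            raise ValueError("reference series length mismatch")
        rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return pred, rmse


def fit_area_estimator(
    area_series,
    foci_series,
    a_s: float,
    train_window: Optional[Tuple[int, int]] = None,
) -> Tuple[EstimatorParams, float]:
    """Least-squares fit of (m, b, phi, a0) on a training window.

    *train_window* is an index slice ``(start, stop)`` into the aligned
    series; the recursion is anchored at ``start`` (``Abar(t_start) = a0``).
    Returns the parameters and the training-window RMSE.
    """
    area = np.asarray(area_series, dtype=float)
    foci = np.asarray(foci_series, dtype=float)
    if area.shape != foci.shape:
        raise ValueError("area and foci series must be aligned")
    if train_window is None:
        train_window = (0, len(area))
    start, stop = train_window
    if not (0 <= start < stop <= len(area)):
        raise ValueError("train_window out of range")
    y = area[start:stop]
    f = foci[start:stop]

    def solve(phi: float):
        h_a0, h_m, h_b, offset = _recursion_basis(f, phi, a_s)
        design = np.column_stack([h_a0, h_m, h_b])
        coef, _, _, _ = np.linalg.lstsq(design, y - offset, rcond=None)
        resid = design @ coef + offset - y
        return coef, float(resid @ resid)

    # profile out (a0, m, b); line-search the remaining SSE(phi) on [0, 1]
    grid = np.concatenate([[0.0], np.geomspace(1e-6, 1.0, 120)])
    sses = np.array([solve(p)[1] for p in grid])
    best = int(np.argmin(sses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    result = optimize.minimize_scalar(
        lambda p: solve(p)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    phi = float(np.clip(result.x, 0.0, 1.0))
    if result.fun > sses[best]:
        phi = float(grid[best])

    # parabolic polish: the recursion accumulates phi errors over the whole
    # window, so the scalar search is refined well below its xatol
    h = 1e-6
    for _ in range(6):
        p0 = max(phi - h, 0.0)
        p2 = min(phi + h, 1.0)
        s0, s1, s2 = solve(p0)[1], solve(phi)[1], solve(p2)[1]
        denom = (s0 - 2.0 * s1 + s2)
        if denom > 0.0:
            step = 0.5 * (s0 - s2) / denom * h
            cand = float(np.clip(phi + step, 0.0, 1.0))
            if solve(cand)[1] <= s1:
                phi = cand
        h *= 1e-2
    coef, sse = solve(phi)
    params = EstimatorParams(m=float(coef[1]), b=float(coef[2]),
                             phi=phi, a0=float(coef[0]), a_s=float(a_s))
    rmse = float(np.sqrt(sse / len(y)))
    return params, rmse


def delta_area_regression(area_series, foci_series):
    """OLS of per-step area change on the concurrent focus count.

    Returns the full :func:`scipy.stats.linregress` result for
    ``diff(area)[j] ~ n_f(t_{j+1})``.
    """
    area = np.asarray(area_series, dtype=float)
    foci = np.asarray(foci_series, dtype=float)
    return stats.linregress(foci[1:], np.diff(area))


class AreaEstimator:
    """Model-style wrapper around the recursive area estimator.

    Parameters
    ----------
    area, foci : array-like
        Aligned per-step area (μm²) and active-focus-count series.
    a_s : float
        Resting area (μm²).
    """

    def __init__(self, area, foci, a_s: float):
        self.area = np.asarray(area, dtype=float)
        self.foci = np.asarray(foci, dtype=float)
        self.a_s = float(a_s)

    @classmethod
    def from_trace(cls, trace: SimulationTrace) -> "AreaEstimator":
        return cls(trace.area, trace.n_f, trace.a_s)

    def fit(self, train_window: Optional[Tuple[int, int]] = None) -> "AreaEstimatorResults":
        params, rmse = fit_area_estimator(self.area, self.foci, self.a_s,
                                          train_window)
        return AreaEstimatorResults(self, params, rmse, train_window)


class AreaEstimatorResults:
    """Fit results: parameters, training RMSE, prediction and summary."""

    def __init__(self, model: AreaEstimator, params: EstimatorParams,
                 rmse: float, train_window):
        self.model = model
        self.params = params
        self.rmse = rmse
        self.train_window = train_window or (0, len(model.area))

    def predict(self, foci_series=None, reference=None):
        if foci_series is None:
            foci_series = self.model.foci
        return predict_area(self.params, foci_series, reference)

    def summary(self) -> str:
        p = self.params
        start, stop = self.train_window
        lines = [
            "Recursive foci-count area estimator",
            "===================================",
            f"training window        [{start}, {stop})  ({stop - start} steps)",
            f"resting area A_s       {p.a_s:.6g} μm²",
            f"m (per focus, step)    {p.m:.6g} μm²",
            f"b (baseline, step)     {p.b:.6g} μm²",
            f"Phi (decay per step)   {p.phi:.6g}",
            f"A0 (initial estimate)  {p.a0:.6g} μm²",
            f"training RMSE          {self.rmse:.6g} μm²",
        ]
        return "\n".join(lines)
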