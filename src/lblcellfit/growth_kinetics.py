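"""Logistic growth fitting, two-line lag estimation, plate normalization.

The population model is the logistic curve

    N(t) = K / (1 + ((K - N0)/N0) exp(-r t))

with carrying capacity K, initial size N0 and intrinsic rate r; derived
quantities are tmid = ln((K-N0)/N0)/r (time to K/2), tgen = ln 2 / r
(fastest doubling time) and the area under the curve, reported both as
the integral of the fitted curve and as the trapezoid on the data.

The lag duration (lambda) is the time-axis coordinate where two
regression lines intersect: one through the lag-phase points, one
through the exponential-phase points.  Segments grow forward one point
at a time from the first point (then from the first excluded point) and
stop when the segment's R^2 falls more than `r2_drop` below the best R^2
the segment has shown; a segment whose raw-signal spread is below
`flat_tol` of the curve's dynamic range is treated as zero-variance
(R^2 := 1), which lets flat lag phases extend through measurement noise.
By default both lines are fitted to log(signal), where the exponential
phase is genuinely linear and the intersection with the flat baseline is
an unbiased estimate of the lag end; `scale="raw"` fits the lines to the
untransformed signal (appropriate for piecewise-linear data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class LagEstimationError(ValueError):
    """Two-line lag estimation failed (no break, or segments unusable)."""


class LogisticFitError(RuntimeError):
    """Logistic least squares failed or found no growth."""


@dataclass
class GrowthCurve:
    """A single replicate growth curve with declared units."""

    time: np.ndarray
    signal: np.ndarray
    time_unit: str = "h"
    signal_unit: str = "OD"
    fluorescence: np.ndarray | None = None
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class LogisticFit:
    K: float
    N0: float
    r: float
    tmid: float
    tgen: float
    auc_l: float
    auc_e: float
    rss: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = (self.K - self.N0) / self.N0
        return self.K / (1.0 + a * np.exp(-self.r * t))

    def as_dict(self) -> dict:
        return {
            "K": self.K, "N0": self.N0, "r": self.r, "tmid": self.tmid,
            "tgen": self.tgen, "auc_l": self.auc_l, "auc_e": self.auc_e,
            "rss": self.rss,
        }


@dataclass
class LagEstimate:
    lambda_lag: float
    lag_segment: tuple[int, int]  # half-open index range
    exp_segment: tuple[int, int]
    line1: tuple[float, float]  # slope, intercept (regression scale)
    line2: tuple[float, float]
    r2_trace_lag: list[float]
    r2_trace_exp: list[float]
    scale: str = "log"
    out_of_range: bool = False


def _logistic(t, K, N0, r):
    a = (K - N0) / N0
    return K / (1.0 + a * np.exp(-r * t))


def fit_logistic(curve: GrowthCurve | tuple, init=None) -> LogisticFit:
    """Least-squares logistic fit with data-driven multi-start.

    Starts combine K ~ max(signal), N0 ~ first positive value and r from
    the log-slope of the middle third, each varied over a small factor
    grid; parameters are optimized in log space to stay positive.
    """
    if isinstance(curve, tuple):
        curve = GrowthCurve(time=curve[0], signal=curve[1])
    t, y = curve.time, curve.signal
    if t.size < 6:
        raise ValueError("need at least 6 points to fit")
    ypos = y[y > 0]
    if ypos.size == 0 or np.ptp(y) <= 0:
        raise LogisticFitError("no growth: signal has no positive dynamic range")

    K0 = float(y.max())
    N00 = float(ypos[0])
    third = slice(t.size // 3, 2 * t.size // 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.log(np.clip(y, 1e-12, None))
    dt = t[third][-1] - t[third][0]
    r0 = float((logy[third][-1] - logy[third][0]) / dt) if dt > 0 else 1.0
    r0 = max(r0, 1e-3)

    if init is not None:
        starts = [tuple(init)]
    else:
        starts = [
            (K0, n0f * N00, rf * r0)
            for rf in (0.5, 1.0, 2.0)
            for n0f in (1.0, 0.1)
        ]

    def resid(theta):
        # clip so LM line searches cannot overflow exp()
        K, N0, r = np.exp(np.clip(theta, -40.0, 40.0))
        return _logistic(t, K, N0, r) - y

    best = None
    for K_s, N0_s, r_s in starts:
        x0 = np.log([max(K_s, 1e-9), max(N0_s, 1e-12), max(r_s, 1e-6)])
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                sol = optimize.least_squares(
                    resid, x0=x0, method="lm", xtol=1e-15, ftol=1e-15
                )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise LogisticFitError("logistic fit did not converge from any start")

    K, N0, r = (float(v) for v in np.exp(best.x))
    if K <= N0 * (1.0 + 1e-9):
        raise LogisticFitError("no growth: fitted K <= N0")
    a = (K - N0) / N0
    tmid = float(np.log(a) / r)
    tgen = float(np.log(2.0) / r)
    T0, T1 = float(t[0]), float(t[-1])
    # closed-form integral of the logistic between the data endpoints
    auc_l = float(
        K * (T1 - T0) - (K / r) * (
            np.log1p(a * np.exp(-r * T0)) - np.log1p(a * np.exp(-r * T1))
        )
    )
    auc_e = float(np.trapezoid(y, t))
    rss = float(2.0 * best.cost)
    return LogisticFit(K=K, N0=N0, r=r, tmid=tmid, tgen=tgen,
                       auc_l=auc_l, auc_e=auc_e, rss=rss)


def _segment_r2(t, y):
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 1.0
    m, b = np.polyfit(t, y, 1)
    ssr = float(((y - (m * t + b)) ** 2).sum())
    return 1.0 - ssr / sst


def _extend_segment(t, y, y_raw, start, min_points, r2_drop, floor):
    """Grow [start, end) while R^2 stays within r2_drop of its best value."""

    def seg_r2(a, b):
        if float(y_raw[a:b].std()) <= floor:
            return 1.0  # effectively zero-variance: flat within noise
        return _segment_r2(t[a:b], y[a:b])

    end = start + min_points
    trace = [seg_r2(start, end)]
    best = trace[0]
    while end < t.size:
        r2_new = seg_r2(start, end + 1)
        if r2_new < best - r2_drop:
            break
        end += 1
        trace.append(r2_new)
        best = max(best, r2_new)
    return end, trace


def estimate_lag(
    curve: GrowthCurve | tuple,
    min_points: int = 3,
    r2_drop: float = 0.01,
    scale: str = "log",
    flat_tol: float = 0.01,
) -> LagEstimate:
    """Two-line changepoint estimate of the lag duration.

    Returns the intersection time of the lag-phase and exponential-phase
    regression lines, together with both segments and their full R^2
    traces for auditing the breakpoints.
    """
    if isinstance(curve, tuple):
        curve = GrowthCurve(time=curve[0], signal=curve[1])
    t, y_raw = curve.time, curve.signal
    if t.size < 2 * min_points:
        raise ValueError(f"need at least {2 * min_points} points")

    # flatness floor: a segment is "zero-variance" when its spread is
    # within flat_tol of the dynamic range or within twice the robust
    # point-to-point noise (lower-quartile successive difference, which
    # stays noise-dominated as long as ~a quarter of the series is flat)
    sigma_hat = float(
        np.quantile(np.abs(np.diff(y_raw)), 0.25) / (0.3186 * np.sqrt(2.0))
    )
    floor = max(flat_tol * float(np.ptp(y_raw)), 2.0 * sigma_hat)

    if scale == "log":
        # clip below half the flatness floor: keeps log(baseline) bounded
        # when noise carries points to or below zero
        clip = max(0.5 * floor, 1e-12)
        y = np.log(np.clip(y_raw, clip, None))
    elif scale == "raw":
        y = y_raw
    else:
        raise ValueError(f"unknown scale {scale!r}")
    e1, trace1 = _extend_segment(t, y, y_raw, 0, min_points, r2_drop, floor)
    if t.size - e1 < min_points:
        raise LagEstimationError(
            "no usable exponential segment after the lag phase "
            "(curve may have no break)"
        )
    e2, trace2 = _extend_segment(t, y, y_raw, e1, min_points, r2_drop, floor)

    m1, b1 = np.polyfit(t[:e1], y[:e1], 1)
    m2, b2 = np.polyfit(t[e1:e2], y[e1:e2], 1)
    slope_scale = max(abs(m1), abs(m2), 1e-12)
    if abs(m2 - m1) < 1e-9 * slope_scale or m2 == m1:
        raise LagEstimationError("regression lines are parallel: no lag break")
    lam = float((b1 - b2) / (m2 - m1))
    out_of_range = not (t[0] <= lam <= t[e2 - 1])
    if out_of_range:
        warnings.warn(
            f"lag estimate {lam:.3g} lies outside the fitted segments",
            RuntimeWarning,
        )
    return LagEstimate(
        lambda_lag=lam,
        lag_segment=(0, int(e1)),
        exp_segment=(int(e1), int(e2)),
        line1=(float(m1), float(b1)),
        line2=(float(m2), float(b2)),
        r2_trace_lag=[float(v) for v in trace1],
        r2_trace_exp=[float(v) for v in trace2],
        scale=scale,
        out_of_range=out_of_range,
    )


def plot_lag_fit(curve: "GrowthCurve", estimate: "LagEstimate", path=None):
    """Plot a growth curve with its two regression lines and lag marker.

    Requires matplotlib (optional dependency); returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, y = curve.time, curve.signal
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t, y, "o", ms=3, color="0.4", label="signal")
    if estimate.scale == "log":
        ax.set_yscale("log")
        to_y = np.exp
    else:
        to_y = lambda v: v  # noqa: E731
    for (m, b), (i0, i1), label in (
        (estimate.line1, estimate.lag_segment, "lag line"),
        (estimate.line2, estimate.exp_segment, "exponential line"),
    ):
        tt = np.linspace(t[i0], t[min(i1, t.size - 1)], 50)
        ax.plot(tt, to_y(m * tt + b), lw=1.5, label=label)
    ax.axvline(estimate.lambda_lag, ls="--", color="k", lw=1,
               label=f"lag = {estimate.lambda_lag:.2f} {curve.time_unit}")
    ax.set_xlabel(f"time ({curve.time_unit})")
    ax.set_ylabel(f"signal ({curve.signal_unit})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def normalize_plate_signals(
    raw: pd.DataFrame,
    blank_condition: str = "blank",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Blank-correct OD and express fluorescence relative to the control.

    od_norm(t) = od(t) - mean blank od(t);
    fluor_norm(t) = fluorescence(t) / mean control fluorescence(t),
    so the control's normalized fluorescence is identically 1 (up to
    replicate scatter).
    """
    required = {"time_h", "od", "condition", "replicate"}
    if not required.issubset(raw.columns):
        raise ValueError(f"plate table needs columns {sorted(required)}")
    blanks = raw[raw["condition"] == blank_condition]
    controls = raw[raw["condition"] == control_condition]
    if blanks.empty or controls.empty:
        raise ValueError("blank and control conditions must both be present")

    blank_mean = blanks.groupby("time_h")["od"].mean()
    out = raw.copy()
    out["od_norm"] = out["od"] - out["time_h"].map(blank_mean)
    if "fluorescence" in raw.columns:
        ctrl_mean = controls.groupby("time_h")["fluorescence"].mean()
        if (ctrl_mean <= 0).any():
            raise ValueError(
                "control fluorescence is non-positive at some time points"
            )
        out["fluor_norm"] = out["fluorescence"] / out["time_h"].map(ctrl_mean)
    return out


def peak_fluorescence_ratio(
    raw: pd.DataFrame,
    condition: str,
    control_condition: str = "control",
) -> float:
    """Peak fluorescence of a condition relative to the control's peak.

    Uses the maximum over time of the replicate-mean fluorescence, the
    condition-level statistic reported for expression comparisons.
    """
    def peak(name: str) -> float:
        sub = raw[raw["condition"] == name]
        if sub.empty:
            raise ValueError(f"condition {name!r} not in table")
        return float(sub.groupby("time_h")["fluorescence"].mean().max())

    return peak(condition) / peak(control_condition)


def curves_from_plate(
    table: pd.DataFrame,
    signal_column: str = "od_norm",
) -> list[GrowthCurve]:
    """Split a (normalized) tidy plate table into replicate GrowthCurves."""
    curves = []
    for (cond, rep), sub in table.groupby(["condition", "replicate"], sort=True):
        if cond == "blank":
            continue
        sub = sub.sort_values("time_h")
        curves.append(
            GrowthCurve(
                time=sub["time_h"].to_numpy(),
                signal=sub[signal_column].to_numpy(),
                time_unit="h",
                signal_unit="OD",
                fluorescence=sub["fluorescence"].to_numpy()
                if "fluorescence" in sub
                else None,
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return curves


def compare_conditions(
    params: pd.DataFrame,
    control_condition: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition summaries and Welch t-tests against the control.

    `params` is tidy: one row per replicate with a ``condition`` column
    and numeric parameter columns (lambda_lag, r, K, tmid, tgen, auc...).
    Returns (summary, tests); `tests` is empty when only one condition or
    fewer than two replicates are present.
    """
    value_cols = [
        c for c in params.columns
        if c not in ("condition", "replicate") and pd.api.types.is_numeric_dtype(params[c])
    ]
    summary = (
        params.groupby("condition")[value_cols]
        .agg(["mean", "std", "count"])
        .sort_index()
    )
    tests = []
    conditions = [c for c in params["condition"].unique() if c != control_condition]
    ctrl = params[params["condition"] == control_condition]
    if not ctrl.empty:
        for cond in conditions:
            grp = params[params["condition"] == cond]
            if len(grp) < 2 or len(ctrl) < 2:
                continue
            for col in value_cols:
                tstat, p = stats.ttest_ind(
                    grp[col], ctrl[col], equal_var=False
                )
                tests.append(
                    {
                        "condition": cond,
                        "vs": control_condition,
                        "parameter": col,
                        "t_stat": float(tstat),
                        "p_value": float(p),
                    }
                )
    return summary, pd.DataFrame(tests)
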