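"""First-derivative-adaptation statistics and trajectory (bearing/reversal) analytics.

Two families of analysis live here.

*Trace-side*: sigmoidal (tanh) gradients have a first derivative that rises to
a maximum at the gradient midpoint and falls symmetrically after it.  A neuron
that codes the instantaneous derivative should respond symmetrically about the
midpoint; a neuron that ADAPTS to the derivative's magnitude responds more
strongly before the midpoint (while the derivative is still growing) than
after.  The pre/post midpoint activity means and their paired Wilcoxon
comparison quantify that asymmetry.  Pulse amplitude / inter-pulse-interval
correlations against the sensed derivative cover the exponential-ramp
experiments.

*Trajectory-side*: angular deviation between the (smoothed) velocity vector
and the instantaneous direct path to the target; abrupt deviation increases
mark reversal events; reversals are then placed within the rising or falling
phase of the concurrent calcium pulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .errors import DataError, ParameterError, UndefinedTestError
from .pulses import CalciumTrace
from .stimulus import StimulusProfile

__all__ = [
    "Trajectory",
    "DeviationSeries",
    "pre_post_midpoint_means",
    "wilcoxon_test",
    "pulse_derivative_correlation",
    "smooth_track",
    "angular_deviation",
    "detect_reversals",
    "pulse_phase_of_reversals",
]


@dataclass
class Trajectory:
    """A 2-D worm track with a fixed target (odor source) coordinate."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    target: tuple[float, float]
    trace: CalciumTrace | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise DataError("times, x, y must share a shape")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("trajectory times must be strictly increasing")
        if not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.times))
        ):
            raise DataError("trajectory contains non-finite coordinates")


@dataclass
class DeviationSeries:
    """Angular deviation (degrees, [0, 180]) from the direct path to target.

    Samples where the velocity is zero are NaN-masked.
    """

    times: np.ndarray
    deviation: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.deviation = np.asarray(self.deviation, float)
        finite = np.isfinite(self.deviation)
        if np.any((self.deviation[finite] < -1e-9) | (self.deviation[finite] > 180 + 1e-9)):
            raise DataError("deviation must lie in [0, 180] degrees")


def pre_post_midpoint_means(
    trace: CalciumTrace,
    stimulus: StimulusProfile,
    window: float = 150.0,
) -> tuple[float, float]:
    """Mean normalised activity before vs after the point of maximal dC/dt.

    With t* the time of the stimulus' maximal first derivative, returns the
    activity means over [t* - window, t*) and (t*, t* + window] — the sample
    at t* itself belongs to neither side.  The default window is 150 s
    (2.5 min) on each side.

    Raises an error if less than half of either window is covered by the
    trace; partial coverage above that is allowed with a warning.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    d1 = stimulus.require_d1()
    t_star = float(stimulus.times[int(np.argmax(d1))])
    t = trace.times
    before = (t >= t_star - window) & (t < t_star)
    after = (t > t_star) & (t <= t_star + window)
    expected = window / trace.dt
    for name, mask in (("before", before), ("after", after)):
        cover = mask.sum() / expected
        if cover < 0.5:
            raise DataError(
                f"trace covers only {cover:.0%} of the {name}-midpoint window"
            )
        if cover < 0.999:
            warnings.warn(
                f"{name}-midpoint window truncated to {cover:.0%} coverage",
                stacklevel=2,
            )
    return float(trace.values[before].mean()), float(trace.values[after].mean())


def wilcoxon_test(
    a,
    b=None,
    mode: str = "signed_rank_paired",
    side: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon tests with exact small-sample enumeration.

    Parameters
    ----------
    a, b : arrays
        Paired samples (signed-rank) or two independent samples (rank-sum).
        For the signed-rank test ``b`` may be omitted, in which case ``a``
        is taken as the paired differences.
    mode : {"signed_rank_paired", "rank_sum_independent"}
    side : {"two-sided", "greater", "less"}
        For the signed-rank test, "greater" means a tends to exceed b.

    Returns
    -------
    (statistic, p_value)

    Notes
    -----
    Zero differences are dropped (Wilcoxon's convention).  The exact null
    distribution is enumerated when samples are small and tie-free
    (signed-rank n <= 25; rank-sum n*m <= 400); otherwise the normal
    approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    if mode == "signed_rank_paired":
        d = a if b is None else a - np.asarray(b, dtype=float)
        if b is not None and len(a) != len(np.asarray(b)):
            raise ParameterError("paired samples must have equal length")
        d = d[d != 0]
        if d.size == 0:
            raise UndefinedTestError("all paired differences are zero")
        n = d.size
        ties = len(np.unique(np.abs(d))) < n
        method = "exact" if (n <= 25 and not ties) else "approx"
        res = stats.wilcoxon(
            d, alternative=side, method=method, correction=(method == "approx")
        )
        return float(res.statistic), float(res.pvalue)
    if mode == "rank_sum_independent":
        if b is None:
            raise ParameterError("rank-sum test needs two samples")
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise UndefinedTestError("rank-sum test needs non-empty samples")
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=side, method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def pulse_derivative_correlation(
    pulse_table: pd.DataFrame,
    stimulus: StimulusProfile,
    quantity: str = "amplitude",
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between the stimulus first derivative at pulse peaks and a pulse metric.

    ``quantity`` is "amplitude" or "interval"; values are normalised per worm
    (see :func:`pulsenav.pulses.pulse_metrics`) and pooled across worms.
    Returns (r, p) with p from the t-approximation (Pearson, default) or the
    Spearman equivalent.
    """
    from .pulses import pulse_metrics

    col = {"amplitude": "norm_amplitude", "interval": "norm_interval"}.get(quantity)
    if col is None:
        raise ValueError(f"unknown quantity {quantity!r}")
    metrics = pulse_metrics(pulse_table)
    d1 = stimulus.require_d1()
    tab = metrics.dropna(subset=[col])
    if len(tab) < 3:
        raise DataError("need at least 3 pulses for a correlation")
    x = np.interp(tab["peak_time_s"].to_numpy(), stimulus.times, d1)
    y = tab[col].to_numpy(dtype=float)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def smooth_track(traj: Trajectory, roughness: float | str = "auto") -> Trajectory:
    """Penalised least-squares (smoothing-spline) denoising of a track.

    Worm centroid tracks carry large side-to-side head swings; each coordinate
    is smoothed with a cubic smoothing spline that trades squared residuals
    against integrated squared curvature.  ``roughness`` is the penalty λ:
    0 interpolates exactly, large values approach the least-squares straight
    line, and "auto" selects λ by generalized cross-validation.
    """
    if traj.times.size < 4:
        raise DataError("need at least 4 points to smooth a track")
    if np.any(np.diff(traj.times) == 0):
        raise DataError("duplicate timestamps")
    lam = None if roughness == "auto" else float(roughness)
    xs = make_smoothing_spline(traj.times, traj.x, lam=lam)(traj.times)
    ys = make_smoothing_spline(traj.times, traj.y, lam=lam)(traj.times)
    return Trajectory(traj.times, xs, ys, traj.target, traj.trace)


def angular_deviation(traj: Trajectory) -> DeviationSeries:
    """Angle (degrees) between the velocity vector and the direct path to target.

    Velocity uses central differences (one-sided at the ends).  0° means the
    worm heads straight at the target, 180° straight away; samples with zero
    speed are NaN.
    """
    vx = np.gradient(traj.x, traj.times)
    vy = np.gradient(traj.y, traj.times)
    tx = traj.target[0] - traj.x
    ty = traj.target[1] - traj.y
    speed = np.hypot(vx, vy)
    dist = np.hypot(tx, ty)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (vx * tx + vy * ty) / (speed * dist)
    cosang = np.clip(cosang, -1.0, 1.0)
    dev = np.degrees(np.arccos(cosang))
    dev[speed == 0] = np.nan
    dev[dist == 0] = np.nan
    return DeviationSeries(traj.times, dev)


def detect_reversals(
    dev: DeviationSeries, jump: float = 90.0, horizon: float = 1.0
) -> np.ndarray:
    """Times of abrupt deviation increases (reversal events).

    An event is scored at the first time the deviation has risen by at least
    ``jump`` degrees relative to some sample no more than ``horizon`` seconds
    earlier.  Events closer together than ``horizon`` are merged (earliest
    kept).
    """
    if jump <= 0 or horizon <= 0:
        raise ParameterError("jump and horizon must be positive")
    t = dev.times
    d = dev.deviation
    if t.size < 2:
        return np.array([])
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(horizon / dt)))
    events = []
    for i in range(1, t.size):
        lo = max(0, i - w)
        ref = np.nanmin(d[lo:i]) if np.any(np.isfinite(d[lo:i])) else np.nan
        if np.isfinite(ref) and np.isfinite(d[i]) and d[i] - ref >= jump:
            events.append(t[i])
    if not events:
        return np.array([])
    merged = [events[0]]
    for e in events[1:]:
        if e - merged[-1] > horizon:
            merged.append(e)
    return np.asarray(merged)


def pulse_phase_of_reversals(
    trace: CalciumTrace,
    dev: DeviationSeries,
    events: np.ndarray,
    peak_indices: np.ndarray,
) -> pd.DataFrame:
    """Place reversal events within the rising or falling phase of each pulse.

    Each pulse spans from the activity trough preceding its peak to the
    trough before the next peak (trace start/end at the flanks) and is split
    at the peak sample; the peak itself belongs to the second (falling)
    half.  For every pulse the maximal angular deviation in
    each half is reported; every event inside a pulse is annotated with the
    normalised activity (fraction of that pulse's peak value) at the event
    time.  Events outside any pulse are labelled "between-pulse".

    Returns
    -------
    DataFrame with one row per (pulse, half) plus one row per event:
        kind = "half": pulse_index, half ("first"/"second"), max_deviation
        kind = "event": pulse_index (-1 if between pulses), event_time_s,
        half, activity_fraction
    """
    peak_indices = np.asarray(peak_indices, dtype=int)
    rows: list[dict] = []
    t = trace.times
    if peak_indices.size == 0:
        for e in np.atleast_1d(events):
            rows.append(
                {
                    "kind": "event",
                    "pulse_index": -1,
                    "half": "between-pulse",
                    "event_time_s": float(e),
                    "activity_fraction": np.nan,
                    "max_deviation": np.nan,
                }
            )
        return pd.DataFrame(rows)

    # pulse spans: activity troughs between adjacent peaks
    edges = np.empty(peak_indices.size + 1)
    edges[0] = t[0]
    edges[-1] = t[-1]
    for k in range(peak_indices.size - 1):
        lo, hi = peak_indices[k], peak_indices[k + 1]
        edges[k + 1] = t[lo + int(np.argmin(trace.values[lo:hi]))]

    dev_t, dev_v = dev.times, dev.deviation
    for k, p in enumerate(peak_indices):
        t_peak = t[p]
        for half, lo, hi in (
            ("first", edges[k], t_peak),
            ("second", t_peak, edges[k + 1]),
        ):
            # the peak sample itself counts toward the second half
            mask = (
                (dev_t >= lo) & (dev_t < hi)
                if half == "first"
                else (dev_t >= lo) & (dev_t <= hi)
            )
            vals = dev_v[mask]
            md = float(np.nanmax(vals)) if np.any(np.isfinite(vals)) else np.nan
            rows.append(
                {
                    "kind": "half",
                    "pulse_index": k,
                    "half": half,
                    "max_deviation": md,
                    "event_time_s": np.nan,
                    "activity_fraction": np.nan,
                }
            )
    peak_vals = trace.values[peak_indices]
    for e in np.atleast_1d(events):
        k = int(np.searchsorted(edges, e, side="right")) - 1
        k = min(max(k, 0), peak_indices.size - 1)
        if e < edges[0] or e > edges[-1]:
            half, k_out = "between-pulse", -1
            frac = np.nan
        else:
            half = "second" if e >= t[peak_indices[k]] else "first"
            k_out = k
            act = float(np.interp(e, t, trace.values))
            frac = act / peak_vals[k] if peak_vals[k] > 0 else np.nan
        rows.append(
            {
                "kind": "event",
                "pulse_index": k_out,
                "half": half,
                "event_time_s": float(e),
                "activity_fraction": frac,
                "max_deviation": np.nan,
            }
        )
    return pd.DataFrame(rows)
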