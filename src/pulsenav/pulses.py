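"""Calcium-trace pulse analytics: normalisation, detection, decay fitting, metrics.

AWA-class chemosensory neurons respond to smoothly rising odor gradients with
discrete calcium transients ("pulses"): a sharp rise followed by an
exponential decay A·exp(-t/τ).  This module detects pulses in fluorescence
traces, fits the decay to extract amplitude A and decay constant τ, and
computes the per-animal normalised metrics used downstream by the
individuality and adaptation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import DataError, DegenerateTraceError, FitError, ParameterError

__all__ = [
    "CalciumTrace",
    "Pulse",
    "normalize_trace",
    "detect_pulses",
    "fit_pulse_decay",
    "half_decay_time",
    "empirical_half_decay_time",
    "pulse_metrics",
    "extract_pulses",
]

#: nominal imaging rate (frames/s) of the single-neuron recordings
DEFAULT_FRAME_RATE = 1.4

#: default peak prominence, as a fraction of the trace range
DEFAULT_MIN_PROMINENCE = 0.2

#: default minimal peak separation (s); pulses last tens of seconds
DEFAULT_MIN_SEPARATION = 10.0


@dataclass
class CalciumTrace:
    """A single neuron's fluorescence time course for one animal.

    times are seconds on a uniform grid (nominally 1.4 Hz); values are
    fluorescence in arbitrary units, non-negative, NaN-free.
    """

    worm_id: str
    neuron: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError("times and values must be 1-D and equal length")
        if self.times.size < 2:
            raise DataError("trace needs at least two samples")
        if np.any(~np.isfinite(self.values)) or np.any(~np.isfinite(self.times)):
            raise DataError("trace contains NaN/inf values")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise DataError("trace times must be strictly increasing")
        if not np.allclose(steps, np.median(steps), rtol=1e-3, atol=1e-9):
            # resample to the median interval rather than reject outright
            dt = float(np.median(steps))
            new_t = np.arange(self.times[0], self.times[-1] + dt / 2, dt)
            self.values = np.interp(new_t, self.times, self.values)
            self.times = new_t
            warnings.warn(
                f"trace {self.worm_id}/{self.neuron}: non-uniform sampling "
                f"resampled to {dt:.4g} s by linear interpolation",
                stacklevel=2,
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class Pulse:
    """One detected calcium transient and its fitted decay."""

    worm_id: str
    peak_time: float
    amplitude: float  # a.u. above local baseline
    tau: float  # decay constant, s
    fit_rmse: float
    interval_to_next: float | None = None  # peak-to-peak, s
    converged: bool = True
    extra: dict = field(default_factory=dict)


def normalize_trace(values: np.ndarray) -> np.ndarray:
    """Min-max normalise a series to [0, 1]: (v - min) / (max - min).

    Raises :class:`DegenerateTraceError` for a constant series.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("cannot normalise an empty series")
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        raise DegenerateTraceError("constant trace cannot be min-max normalised")
    return (v - lo) / (hi - lo)


def detect_pulses(
    trace: CalciumTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> np.ndarray:
    """Locate pulse peaks as prominent local maxima.

    Parameters
    ----------
    min_prominence : float
        Required prominence as a fraction of the trace's full range.
    min_separation : float
        Minimal peak-to-peak distance in seconds.

    Returns
    -------
    ndarray of int
        Peak sample indices (possibly empty).  Where plateaus tie, the
        earlier sample is reported.
    """
    if min_prominence <= 0 or min_separation <= 0:
        raise ParameterError("detection parameters must be positive")
    rng_ = float(np.max(trace.values) - np.min(trace.values))
    if rng_ == 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation / trace.dt)))
    peaks, _ = find_peaks(
        trace.values, prominence=min_prominence * rng_, distance=distance
    )
    return peaks


def _exp_decay(t, A, tau):
    return A * np.exp(-t / tau)


def fit_pulse_decay(
    trace: CalciumTrace, peak_index: int, fit_end: int
) -> tuple[float, float, float, bool]:
    """Fit A·exp(-t/τ) to the decay following a pulse peak.

    The window runs from ``peak_index`` (t = 0) to ``fit_end`` (exclusive).
    Values are assumed already baseline-subtracted.  The fit is nonlinear
    least squares initialised from a log-linear regression of the positive
    samples (log-linear alone is biased under additive noise).

    Returns
    -------
    (A, tau, rmse, converged)

    Raises
    ------
    FitError
        If the window is too short or the peak value is non-positive.
    """
    if fit_end - peak_index < 4:
        raise FitError("decay fit window needs at least 4 samples")
    y = trace.values[peak_index:fit_end]
    t = trace.times[peak_index:fit_end] - trace.times[peak_index]
    if y[0] <= 0:
        raise FitError("peak value must be positive after baseline subtraction")
    pos = y > 0
    if pos.sum() >= 2:
        # log-linear initial guess on the positive samples
        coef = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else t[-1] if t[-1] > 0 else 1.0
        A0 = float(np.exp(coef[1]))
    else:
        tau0, A0 = max(t[-1], trace.dt), float(y[0])
    tau0 = float(np.clip(tau0, trace.dt / 10, 100 * (t[-1] + trace.dt)))
    converged = True
    try:
        popt, _ = curve_fit(
            _exp_decay,
            t,
            y,
            p0=[max(A0, 1e-12), tau0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=2000,
        )
        A, tau = float(popt[0]), float(popt[1])
    except RuntimeError:
        A, tau, converged = max(A0, 1e-12), tau0, False
    rmse = float(np.sqrt(np.mean((_exp_decay(t, A, tau) - y) ** 2)))
    return A, tau, rmse, converged


def half_decay_time(tau: float) -> float:
    """Analytic half-decay time of an exponential: t_1/2 = τ·ln 2."""
    if tau <= 0:
        raise ParameterError("tau must be positive")
    return float(tau * np.log(2.0))


def empirical_half_decay_time(
    trace: CalciumTrace, peak_index: int, baseline: float = 0.0
) -> float:
    """First crossing of half the peak height (above baseline) after the peak.

    Linear interpolation between the bracketing samples; NaN if the trace
    never falls to half within the recording.
    """
    y = trace.values[peak_index:] - baseline
    t = trace.times[peak_index:] - trace.times[peak_index]
    half = y[0] / 2.0
    below = np.nonzero(y <= half)[0]
    if below.size == 0:
        return float("nan")
    i = below[0]
    if i == 0:
        return 0.0
    # interpolate the crossing between samples i-1 and i
    frac = (y[i - 1] - half) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def pulse_metrics(pulse_table: pd.DataFrame) -> pd.DataFrame:
    """Per-worm normalised pulse metrics.

    Applies, within each worm, the normalisation

        normalized = (x - min(x)) / max(x)

    (note the denominator is the maximum, not the range) to pulse amplitudes
    and, where ``interval_s`` is present, to peak-to-peak intervals.

    Parameters
    ----------
    pulse_table : DataFrame
        Columns ``worm_id``, ``amplitude`` and optionally ``interval_s``.

    Returns
    -------
    DataFrame
        Input copy with ``norm_amplitude`` (and ``norm_interval``) columns.
    """
    if len(pulse_table) == 0:
        raise DataError("empty pulse table")
    out = pulse_table.copy()

    def _norm(x: pd.Series) -> pd.Series:
        mx = x.max()
        if mx == 0:
            raise ParameterError("max amplitude is zero; cannot normalise")
        return (x - x.min()) / mx

    out["norm_amplitude"] = out.groupby("worm_id")["amplitude"].transform(_norm)
    if "interval_s" in out.columns:
        valid = out["interval_s"].notna()
        out["norm_interval"] = np.nan
        if valid.any():
            out.loc[valid, "norm_interval"] = (
                out.loc[valid]
                .groupby("worm_id")["interval_s"]
                .transform(lambda x: (x - x.min()) / x.max())
            )
    return out


def _onset_index(values: np.ndarray, peak: int, left_base: int) -> int:
    """Pulse onset: last sample before the peak at or below 10% of the rise."""
    seg = values[left_base : peak + 1]
    rise = values[peak] - seg.min()
    if rise <= 0:
        return left_base
    thresh = seg.min() + 0.1 * rise
    below = np.nonzero(seg <= thresh)[0]
    return left_base + (int(below[-1]) if below.size else 0)


def extract_pulses(
    trace: CalciumTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    decay_floor: float = 0.1,
) -> list[Pulse]:
    """Detect pulses and fit each decay; the full trace → pulse-table pipeline.

    For each detected peak the local baseline is the median of the 5 samples
    preceding pulse onset (robust to slow drift); the decay-fit window runs
    from the peak to the earlier of the next pulse's onset and the first
    sample below ``decay_floor`` of the amplitude.
    """
    peaks, props = _detect_with_props(trace, min_prominence, min_separation)
    n = trace.values.size
    pulses: list[Pulse] = []
    for j, p in enumerate(peaks):
        onset = _onset_index(trace.values, p, int(props["left_bases"][j]))
        pre = trace.values[max(0, onset - 5) : onset]
        baseline = float(np.median(pre)) if pre.size else float(trace.values[onset])
        amp = float(trace.values[p] - baseline)
        if amp <= 0:
            continue
        next_onset = n
        if j + 1 < len(peaks):
            next_onset = _onset_index(
                trace.values, peaks[j + 1], int(props["left_bases"][j + 1])
            )
        y = trace.values[p:next_onset] - baseline
        below = np.nonzero(y < decay_floor * amp)[0]
        end = p + int(below[0]) + 1 if below.size else next_onset
        end = min(max(end, p + 4), n)
        shifted = CalciumTrace(
            trace.worm_id, trace.neuron, trace.times, trace.values - baseline
        )
        try:
            A, tau, rmse, ok = fit_pulse_decay(shifted, int(p), int(end))
        except FitError:
            continue
        pulses.append(
            Pulse(
                worm_id=trace.worm_id,
                peak_time=float(trace.times[p]),
                amplitude=A,
                tau=tau,
                fit_rmse=rmse,
                converged=ok,
                extra={"peak_index": int(p), "baseline": baseline, "raw_amplitude": amp},
            )
        )
    for a, b in zip(pulses, pulses[1:]):
        a.interval_to_next = b.peak_time - a.peak_time
    return pulses


def _detect_with_props(trace, min_prominence, min_separation):
    if min_prominence <= 0 or min_separation <= 0:
        raise ParameterError("detection parameters must be positive")
    rng_ = float(np.max(trace.values) - np.min(trace.values))
    if rng_ == 0:
        return np.array([], dtype=int), {"left_bases": np.array([], dtype=int)}
    distance = max(1, int(round(min_separation / trace.dt)))
    return find_peaks(
        trace.values, prominence=min_prominence * rng_, distance=distance
    )


def pulses_to_table(pulses: list[Pulse]) -> pd.DataFrame:
    """Flatten a pulse list to the standard pulse-table DataFrame."""
    return pd.DataFrame(
        {
            "worm_id": [p.worm_id for p in pulses],
            "peak_time_s": [p.peak_time for p in pulses],
            "amplitude": [p.amplitude for p in pulses],
            "tau_s": [p.tau for p in pulses],
            "rmse": [p.fit_rmse for p in pulses],
            "interval_s": [
                p.interval_to_next if p.interval_to_next is not None else np.nan
                for p in pulses
            ],
        }
    )
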