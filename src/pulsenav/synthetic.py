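"""Synthetic calcium traces and trajectories with the structure the analyses assume.

These generators emulate the statistical signatures of AWA/AWC recordings so
that every analysis stage is testable end-to-end without recordings:

- per-worm pulsatile signatures: each worm draws a characteristic (amplitude,
  decay) signature from a between-worm distribution and its pulses scatter
  tightly around it — the structure the individuality shuffle test detects;
- derivative-driven pulsing: pulse rate and amplitude follow the positive
  part of a drive signal that is either the stimulus' first derivative
  (non-adapting) or the derivative minus its own running average (adapting);
- AWC-like graded responses anti-correlated with the derivative;
- pulse-gated locomotion: forward runs while the sensory pulse is high,
  reversals emitted once activity decays below a threshold fraction of the
  pulse peak.

All generators are deterministic given their seed and return ground truth
alongside the synthetic measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .adaptation import Trajectory
from .errors import ParameterError
from .pulses import CalciumTrace
from .stimulus import StimulusProfile

__all__ = [
    "WormSignature",
    "CohortHyperParams",
    "synth_pulse_cohort",
    "synth_adaptive_trace",
    "synth_awc_trace",
    "synth_pulse_gated_trajectory",
]

#: imaging rate of single-neuron recordings (frames/s)
FRAME_RATE = 1.4

#: pulse tails are cut once they fall below this fraction of the amplitude,
#: so consecutive pulses are exactly disjoint when spaced beyond the cut
TAIL_CUT = 0.01


@dataclass(frozen=True)
class WormSignature:
    """One animal's characteristic pulse statistics."""

    mean_amplitude: float  # a.u.
    amplitude_cv: float  # within-worm coefficient of variation
    mean_tau: float  # s
    tau_cv: float
    base_rate: float = 1.0  # pulses/min

    def __post_init__(self):
        if min(self.mean_amplitude, self.mean_tau, self.base_rate) <= 0:
            raise ParameterError("signature means and rate must be positive")
        if self.amplitude_cv < 0 or self.tau_cv < 0:
            raise ParameterError("CVs must be non-negative")


@dataclass(frozen=True)
class CohortHyperParams:
    """Population-level distributions the per-worm signatures are drawn from.

    Between-worm CVs exceed within-worm CVs by construction, which is what
    makes "individual" cohorts individual.  Defaults give pulse amplitudes
    around 1 a.u. and decay constants around 20 s, i.e. pulses lasting
    several tens of seconds at the 1.4 Hz imaging rate.
    """

    population_amplitude: float = 1.0
    amplitude_between_cv: float = 0.5
    amplitude_within_cv: float = 0.1
    population_tau: float = 20.0
    tau_between_cv: float = 0.4
    tau_within_cv: float = 0.1
    base_rate: float = 1.0  # pulses/min
    baseline: float = 0.05  # a.u.
    noise_sd: float = 0.0  # a.u.
    frame_rate: float = FRAME_RATE

    def __post_init__(self):
        if min(
            self.population_amplitude,
            self.population_tau,
            self.base_rate,
            self.frame_rate,
        ) <= 0:
            raise ParameterError("hyperparameter means/rates must be positive")
        if min(
            self.amplitude_between_cv,
            self.amplitude_within_cv,
            self.tau_between_cv,
            self.tau_within_cv,
            self.noise_sd,
        ) < 0:
            raise ParameterError("CVs and noise sd must be non-negative")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _render_trace(times, onsets, amps, taus, baseline, noise_sd, rng):
    """Sum of instant-rise, exponential-decay pulses (+ baseline and noise).

    Tails are cut at TAIL_CUT of the amplitude, so a pulse contributes
    nothing beyond tau * ln(1 / TAIL_CUT) after its onset.
    """
    vals = np.full_like(times, baseline)
    for t0, a, tau in zip(onsets, amps, taus):
        rel = times - t0
        seg = (rel >= 0) & (rel <= tau * np.log(1.0 / TAIL_CUT))
        vals[seg] += a * np.exp(-rel[seg] / tau)
    if noise_sd > 0:
        vals = vals + noise_sd * rng.standard_normal(times.size)
    return vals


def synth_pulse_cohort(
    n_worms: int,
    pulses_per_worm: int,
    mode: str = "individual",
    hyperparams: CohortHyperParams | None = None,
    seed: int = 0,
) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Generate a cohort of pulsing worms plus the ground-truth pulse table.

    ``individual`` mode draws a per-worm signature from between-worm
    lognormals and then that worm's pulses from tight within-worm lognormals;
    ``pooled`` mode draws every pulse i.i.d. from the population distribution
    (the exchangeable null of the individuality test).

    Pulse onsets land exactly on grid samples and are spaced beyond the tail
    cut, so with ``noise_sd = 0`` detection + decay fitting recover the
    ground-truth (A, tau) to numerical precision.

    Returns
    -------
    (traces, pulse_table)
        ``pulse_table`` columns: worm_id, peak_time_s, amplitude, tau_s,
        interval_s.
    """
    if n_worms < 1 or pulses_per_worm < 1:
        raise ParameterError("counts must be >= 1")
    if mode not in ("individual", "pooled"):
        raise ParameterError(f"unknown mode {mode!r}")
    hp = hyperparams or CohortHyperParams()
    rng = np.random.default_rng(seed)
    dt = 1.0 / hp.frame_rate
    traces: list[CalciumTrace] = []
    rows = []
    for w in range(n_worms):
        wid = f"worm{w:02d}"
        if mode == "individual":
            amp_mean = float(_lognormal(rng, hp.population_amplitude, hp.amplitude_between_cv))
            tau_mean = float(_lognormal(rng, hp.population_tau, hp.tau_between_cv))
            amps = _lognormal(rng, amp_mean, hp.amplitude_within_cv, pulses_per_worm)
            taus = _lognormal(rng, tau_mean, hp.tau_within_cv, pulses_per_worm)
        else:
            # total pooled spread = between- and within-worm variation combined
            amp_cv = np.sqrt((1 + hp.amplitude_between_cv**2) * (1 + hp.amplitude_within_cv**2) - 1)
            tau_cv = np.sqrt((1 + hp.tau_between_cv**2) * (1 + hp.tau_within_cv**2) - 1)
            amps = _lognormal(rng, hp.population_amplitude, amp_cv, pulses_per_worm)
            taus = _lognormal(rng, hp.population_tau, tau_cv, pulses_per_worm)
        # spacing: previous pulse's tail cut plus an exponential waiting time
        gaps = rng.exponential(60.0 / hp.base_rate, pulses_per_worm)
        onsets = np.empty(pulses_per_worm)
        t_cursor = 5.0 + gaps[0] % 20.0
        for k in range(pulses_per_worm):
            if k > 0:
                t_cursor += taus[k - 1] * np.log(1.0 / TAIL_CUT) + 2.0 + gaps[k]
            # snap onsets onto the sampling grid
            onsets[k] = np.round(t_cursor / dt) * dt
            t_cursor = onsets[k]
        t_end = onsets[-1] + taus[-1] * np.log(1.0 / TAIL_CUT) + 10.0
        times = np.arange(0.0, t_end, dt)
        vals = _render_trace(times, onsets, amps, taus, hp.baseline, hp.noise_sd, rng)
        traces.append(CalciumTrace(wid, "AWA", times, vals))
        for k in range(pulses_per_worm):
            rows.append(
                {
                    "worm_id": wid,
                    "peak_time_s": onsets[k],
                    "amplitude": amps[k],
                    "tau_s": taus[k],
                    "interval_s": (onsets[k + 1] - onsets[k]) if k + 1 < pulses_per_worm else np.nan,
                }
            )
    return traces, pd.DataFrame(rows)


def _ema(signal: np.ndarray, dt: float, memory_s: float) -> np.ndarray:
    """Exponential moving average with time constant ``memory_s``."""
    alpha = dt / memory_s
    out = np.empty_like(signal)
    acc = 0.0
    for i, v in enumerate(signal):
        acc += alpha * (v - acc)
        out[i] = acc
    return out


def synth_adaptive_trace(
    stimulus: StimulusProfile,
    adapt: bool = True,
    memory: float = 60.0,
    gain: float = 1.0,
    peak_rate: float = 4.0,
    tau: float = 8.0,
    seed: int = 0,
    noise_sd: float = 0.01,
    worm_id: str = "worm00",
) -> CalciumTrace:
    """Pulsing trace whose rate and amplitude track an (optionally adapted) drive.

    The drive is s(t) = dC/dt (``adapt`` off) or dC/dt minus its own
    exponential moving average with time constant ``memory`` seconds
    (``adapt`` on); only the positive part drives activity.  Pulses are a
    thinned Bernoulli process: per sample, P(pulse) = rate(t)·dt with
    rate(t) = peak_rate/min at the maximal positive drive, scaled linearly,
    and a refractory hold until the running pulse decays to 10% of its
    amplitude.  Pulse amplitude is ``gain`` times the normalised drive at
    onset.
    """
    d1 = stimulus.require_d1()
    dt = stimulus.dt
    s = d1 - _ema(d1, dt, memory) if adapt else d1.copy()
    pos = np.maximum(s, 0.0)
    scale = pos.max()
    if scale == 0:
        drive = np.zeros_like(pos)
    else:
        drive = pos / scale
    rate_per_s = peak_rate / 60.0
    rng = np.random.default_rng(seed)
    u = rng.random(stimulus.times.size)
    onsets, amps, taus = [], [], []
    hold_until = -np.inf
    for i, t in enumerate(stimulus.times):
        if t < hold_until:
            continue
        if u[i] < rate_per_s * dt * drive[i]:
            onsets.append(t)
            amps.append(gain * drive[i])
            taus.append(tau)
            hold_until = t + tau * np.log(10.0)  # refractory: decay to 10%
    vals = _render_trace(
        stimulus.times, np.array(onsets), np.array(amps), np.array(taus), 0.02, noise_sd, rng
    )
    return CalciumTrace(worm_id, "AWA", stimulus.times.copy(), np.maximum(vals, 0.0))


def synth_awc_trace(
    stimulus: StimulusProfile,
    gain: float = 1.0,
    smoothing: float = 2.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    worm_id: str = "worm00",
) -> CalciumTrace:
    """AWC-like graded trace: smoothed positive part of minus the derivative.

    AWC^ON activity rises when the odor concentration falls, so the trace is
    g(t) = smooth(max(0, -gain * dC/dt)) + noise, anti-correlated with dC/dt.
    ``smoothing`` is a Gaussian kernel width in seconds.
    """
    d1 = stimulus.require_d1()
    rng = np.random.default_rng(seed)
    raw = np.maximum(0.0, -gain * d1)
    if smoothing > 0:
        raw = gaussian_filter1d(raw, smoothing / stimulus.dt)
    vals = raw + noise_sd * rng.standard_normal(raw.size)
    return CalciumTrace(worm_id, "AWCON", stimulus.times.copy(), np.maximum(vals, 0.0))


def synth_pulse_gated_trajectory(
    signature: WormSignature | None = None,
    turn_threshold: float = 0.58,
    seed: int = 0,
    duration: float = 600.0,
    sample_rate: float = 2.0,
    speed: float = 0.15,
    target: tuple[float, float] = (30.0, 0.0),
    heading_jitter_deg: float = 8.0,
    reversal_duration: float = 1.0,
    inter_pulse_gap: float = 4.0,
    worm_id: str = "worm00",
) -> tuple[Trajectory, np.ndarray]:
    """Pulse-gated walker: runs while the sensory pulse is high, reverses below threshold.

    The worm starts at the origin heading for ``target`` (mm).  Its AWA-like
    activity starts each pulse at a peak drawn from ``signature`` and decays
    exponentially; while activity >= turn_threshold * peak the worm runs
    toward the target with small heading jitter.  The first sample at which
    activity drops below the threshold emits a reversal: the worm moves
    directly away from the target (plus jitter) for ``reversal_duration``
    seconds.  The run then resumes while the old pulse keeps decaying for
    ``inter_pulse_gap`` seconds (so inter-pulse troughs fall well below the
    turn threshold), after which a fresh pulse starts.  The walk ends when
    the worm reaches the target (within one step) or at ``duration``.  With
    ``turn_threshold = 0`` the activity never crosses and no reversal is
    ever emitted.

    Returns
    -------
    (trajectory, reversal_times)
        The trajectory carries the linked activity trace; ``reversal_times``
        is the ground-truth array of emitted event times (s).
    """
    sig = signature or WormSignature(
        mean_amplitude=1.0, amplitude_cv=0.2, mean_tau=5.0, tau_cv=0.2
    )
    if not (0.0 <= turn_threshold < 1.0):
        raise ParameterError("turn_threshold must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate))
    times = np.arange(n) * dt
    x = np.zeros(n)
    y = np.zeros(n)
    act = np.zeros(n)
    jitter = np.radians(heading_jitter_deg)
    rev_samples = max(1, int(round(reversal_duration * sample_rate)))

    def new_pulse():
        a = float(_lognormal(rng, sig.mean_amplitude, sig.amplitude_cv))
        tau = float(_lognormal(rng, sig.mean_tau, sig.tau_cv))
        return a, tau

    gap_samples = max(1, int(round(inter_pulse_gap * sample_rate)))
    amp, tau = new_pulse()
    t_pulse = -2.0 * dt  # two silent samples so the first peak is detectable
    reversing = 0
    gap = 0
    armed = True  # one reversal per pulse
    events = []
    end = n
    for i in range(n):
        act[i] = amp * np.exp(-t_pulse / tau) if t_pulse >= 0 else 0.0
        if np.hypot(target[0] - x[i], target[1] - y[i]) <= speed * dt:
            end = i + 1  # arrived: truncate the walk here
            break
        if i + 1 >= n:
            break
        if armed and reversing == 0 and t_pulse >= 0 and act[i] < turn_threshold * amp:
            reversing = rev_samples
            armed = False
            events.append(times[i])
        if reversing > 0:
            bearing = np.arctan2(y[i] - target[1], x[i] - target[0])  # away
            reversing -= 1
            if reversing == 0:
                gap = gap_samples  # run resumes; old pulse keeps decaying
        else:
            bearing = np.arctan2(target[1] - y[i], target[0] - x[i])  # toward
            if gap > 0:
                gap -= 1
                if gap == 0:
                    amp, tau = new_pulse()
                    t_pulse = -dt  # fresh pulse starts next sample
                    armed = True
        heading = bearing + jitter * rng.standard_normal()
        x[i + 1] = x[i] + speed * dt * np.cos(heading)
        y[i + 1] = y[i] + speed * dt * np.sin(heading)
        t_pulse += dt
    times, x, y, act = times[:end], x[:end], y[:end], act[:end]
    trace = CalciumTrace(worm_id, "AWA", times, np.maximum(act, 0.0))
    traj = Trajectory(times, x, y, target, trace=trace)
    return traj, np.asarray(events)
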