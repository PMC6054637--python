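"""Smooth temporal odor gradients and the stirred mixing chamber that delivers them.

A microfluidic delivery system mixes a concentrated stimulus syringe with a
buffer syringe inside a small, continuously stirred chamber whose outflow
bathes the animal's nose.  Treating the chamber as a single well-stirred
compartment of volume ``V`` flushed at total flow ``Q`` gives the dilution ODE

    dC/dt = (Q / V) * (C_in(t) - C)

where ``C_in`` is the (pump-controlled) inflow concentration.  This module
provides analytic profile generators (step, linear ramp, hyperbolic-tangent
sigmoid, sinusoid, exponentially accelerating ramp), a grid-exact exponential
integrator for the chamber ODE, and the inversion that turns a desired output
profile into the stimulus/buffer mixing fraction the pumps must realise.

Units: time in seconds, concentration in µM, chamber volume in µL, total flow
in µL/min (converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DataError, InfeasibleGradientError, ParameterError

__all__ = [
    "ChamberSpec",
    "StimulusProfile",
    "generate_profile",
    "chamber_output",
    "design_mixing_schedule",
    "finite_derivatives",
]


@dataclass(frozen=True)
class ChamberSpec:
    """Physical description of the stirred mixing chamber and its feeds.

    Parameters
    ----------
    volume_uL : float
        Chamber volume in µL (the study setups used 50 or 200 µL).
    total_flow_uL_min : float
        Combined flow of the two syringe pumps in µL/min; assumed constant.
    stim_conc_uM : float
        Odorant concentration in the stimulus syringe (µM).
    buffer_conc_uM : float
        Basal odorant concentration in the buffer syringe (µM); a small
        non-zero basal level improves gradient accuracy at low fractions.
    """

    volume_uL: float
    total_flow_uL_min: float
    stim_conc_uM: float
    buffer_conc_uM: float = 0.0

    def __post_init__(self):
        if self.volume_uL <= 0:
            raise ParameterError("chamber volume must be positive")
        if self.total_flow_uL_min <= 0:
            raise ParameterError("total flow must be positive")
        if not self.stim_conc_uM > self.buffer_conc_uM >= 0:
            raise ParameterError(
                "need stim_conc > buffer_conc >= 0 for a usable dilution range"
            )

    @property
    def rate_per_s(self) -> float:
        """Flush rate Q/V in 1/s."""
        return self.total_flow_uL_min / 60.0 / self.volume_uL


@dataclass
class StimulusProfile:
    """A sensed concentration time course C(t) with optional derivatives.

    ``times`` must be strictly increasing with a uniform step; ``conc`` is the
    concentration in µM at each time point; ``d1`` and ``d2`` hold dC/dt
    (µM/s) and d²C/dt² (µM/s²) when available (analytic for generated
    profiles, finite-difference otherwise).
    """

    times: np.ndarray
    conc: np.ndarray
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ParameterError("profile needs at least two time points")
        if self.conc.shape != self.times.shape:
            raise ParameterError("times and conc must have equal length")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DataError("profile time grid must be uniform")
        if np.any(self.conc < -1e-12):
            raise ParameterError("concentrations must be non-negative")
        for name in ("d1", "d2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ParameterError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def require_d1(self, window: int = 1) -> np.ndarray:
        """Return dC/dt, computing finite differences if not attached."""
        if self.d1 is None:
            filled = finite_derivatives(self, window=window)
            self.d1, self.d2 = filled.d1, filled.d2
        return self.d1


def _tanh_profile(t, baseline, amplitude, t_mid, steepness):
    # sigmoid rising from `baseline` to `baseline + amplitude`, midpoint t_mid
    z = steepness * (t - t_mid)
    conc = baseline + 0.5 * amplitude * (1.0 + np.tanh(z))
    sech2 = 1.0 / np.cosh(z) ** 2
    d1 = 0.5 * amplitude * steepness * sech2
    d2 = -amplitude * steepness**2 * sech2 * np.tanh(z)
    return conc, d1, d2


_GENERATORS: dict[str, Callable] = {}


def generate_profile(kind: str, params: dict, times: np.ndarray) -> StimulusProfile:
    """Generate an analytic stimulus profile with exact first/second derivatives.

    Parameters
    ----------
    kind : {"step", "linear", "tanh", "sinusoid", "exp_derivative"}
        Shape family.
    params : dict
        Shape parameters (all concentrations µM, times s):

        - ``step``: ``baseline``, ``height``, ``t0`` — baseline before ``t0``,
          baseline + height from ``t0`` on.
        - ``linear``: ``baseline``, ``slope`` (µM/s) — ramp from baseline.
        - ``tanh``: ``baseline``, ``amplitude``, ``t_mid``, ``steepness``
          (1/s) — sigmoid whose first derivative peaks exactly at ``t_mid``.
        - ``sinusoid``: ``baseline``, ``amplitude``, ``period`` (s), optional
          ``phase`` (rad) — requires baseline >= amplitude so conc stays >= 0.
        - ``exp_derivative``: ``baseline``, ``c0``, ``tau_growth`` (s) —
          C(t) = baseline + c0*(exp(t/tau_growth) - 1); the first derivative
          grows exponentially in time.
    times : array
        Uniform time grid in seconds.

    Returns
    -------
    StimulusProfile
        With analytic ``d1`` and ``d2`` attached.

    Raises
    ------
    ParameterError
        If the parameters would produce negative concentrations anywhere on
        the grid, or are otherwise invalid.
    ValueError
        If ``kind`` is unknown (usage error).
    """
    t = np.asarray(times, dtype=float)
    if kind not in _GENERATORS:
        raise ValueError(
            f"unknown profile kind {kind!r}; choose from {sorted(_GENERATORS)}"
        )
    conc, d1, d2 = _GENERATORS[kind](t, params)
    if np.any(conc < 0):
        first = t[np.argmax(conc < 0)]
        raise ParameterError(
            f"profile {kind!r} goes negative (first at t = {first:.4g} s); "
            "adjust baseline/amplitude"
        )
    return StimulusProfile(t, conc, d1, d2, meta={"kind": kind, **params})


def _gen_step(t, params):
    baseline = float(params.get("baseline", 0.0))
    height = float(params["height"])
    t0 = float(params.get("t0", 0.0))
    conc = np.where(t >= t0, baseline + height, baseline)
    d1 = np.zeros_like(t)
    d2 = np.zeros_like(t)
    return conc, d1, d2


def _gen_linear(t, params):
    baseline = float(params.get("baseline", 0.0))
    slope = float(params["slope"])  # µM/s
    conc = baseline + slope * (t - t[0])
    d1 = np.full_like(t, slope)
    d2 = np.zeros_like(t)
    return conc, d1, d2


def _gen_tanh(t, params):
    return _tanh_profile(
        t,
        float(params.get("baseline", 0.0)),
        float(params["amplitude"]),
        float(params["t_mid"]),
        float(params["steepness"]),
    )


def _gen_sinusoid(t, params):
    baseline = float(params["baseline"])
    amplitude = float(params["amplitude"])
    period = float(params["period"])
    phase = float(params.get("phase", 0.0))
    if amplitude < 0 or period <= 0:
        raise ParameterError("sinusoid needs amplitude >= 0 and period > 0")
    if baseline < amplitude:
        raise ParameterError("sinusoid needs baseline >= amplitude so conc >= 0")
    w = 2.0 * np.pi / period
    conc = baseline + amplitude * np.sin(w * (t - t[0]) + phase)
    d1 = amplitude * w * np.cos(w * (t - t[0]) + phase)
    d2 = -amplitude * w**2 * np.sin(w * (t - t[0]) + phase)
    return conc, d1, d2


def _gen_exp_derivative(t, params):
    baseline = float(params.get("baseline", 0.0))
    c0 = float(params["c0"])
    tau_g = float(params["tau_growth"])
    if c0 <= 0 or tau_g <= 0:
        raise ParameterError("exp_derivative needs c0 > 0 and tau_growth > 0")
    e = np.exp((t - t[0]) / tau_g)
    conc = baseline + c0 * (e - 1.0)
    d1 = c0 / tau_g * e
    d2 = c0 / tau_g**2 * e
    return conc, d1, d2


_GENERATORS.update(
    step=_gen_step,
    linear=_gen_linear,
    tanh=_gen_tanh,
    sinusoid=_gen_sinusoid,
    exp_derivative=_gen_exp_derivative,
)


def chamber_output(
    inflow: StimulusProfile, chamber: ChamberSpec, c0: float = 0.0
) -> StimulusProfile:
    """Integrate the stirred-chamber dilution ODE for a given inflow profile.

    Uses an exponential integrator that is exact for piecewise-linear inflow:
    over each grid interval of length h with inflow slope s,

        C(t+h) = C_in(t+h) - s/a + exp(-a h) * (C(t) - C_in(t) + s/a),

    a = Q/V.  This is unconditionally stable and reproduces step responses to
    machine precision on the grid.

    Parameters
    ----------
    inflow : StimulusProfile
        Inflow concentration C_in(t) on a uniform grid.
    chamber : ChamberSpec
    c0 : float
        Initial chamber concentration (µM), >= 0.

    Returns
    -------
    StimulusProfile
        Output (chamber exit) concentration on the same grid; finite-difference
        derivatives attached.
    """
    if c0 < 0:
        raise ParameterError("initial concentration must be non-negative")
    a = chamber.rate_per_s
    t = inflow.times
    cin = inflow.conc
    h = inflow.dt
    decay = np.exp(-a * h)
    out = np.empty_like(cin)
    out[0] = c0
    slopes = np.diff(cin) / h
    for k in range(len(t) - 1):
        s = slopes[k]
        out[k + 1] = cin[k + 1] - s / a + decay * (out[k] - cin[k] + s / a)
    prof = StimulusProfile(t, np.maximum(out, 0.0), meta={"kind": "chamber_output"})
    return finite_derivatives(prof)


def design_mixing_schedule(
    target: StimulusProfile, chamber: ChamberSpec
) -> np.ndarray:
    """Invert the chamber model: stimulus fraction f(t) realising a target output.

    The pump pair delivers inflow C_in = C_buf + f*(C_stim - C_buf) with
    f in [0, 1].  Substituting into the chamber ODE and solving for f gives

        f(t) = [ (V/Q) * dC/dt + C(t) - C_buf ] / (C_stim - C_buf).

    Parameters
    ----------
    target : StimulusProfile
        Desired chamber output; its analytic first derivative is used when
        attached, otherwise finite differences are computed.
    chamber : ChamberSpec

    Returns
    -------
    ndarray
        Stimulus fraction per time point, all within [0, 1].

    Raises
    ------
    InfeasibleGradientError
        If any required fraction falls outside [0, 1]; the error names the
        first violating time.
    """
    d1 = target.require_d1()
    a = chamber.rate_per_s
    span = chamber.stim_conc_uM - chamber.buffer_conc_uM
    f = (d1 / a + target.conc - chamber.buffer_conc_uM) / span
    tol = 1e-9
    bad = (f < -tol) | (f > 1 + tol)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise InfeasibleGradientError(target.times[i], f[i])
    return np.clip(f, 0.0, 1.0)


def schedule_to_inflow(
    f: np.ndarray, times: np.ndarray, chamber: ChamberSpec
) -> StimulusProfile:
    """Convert a stimulus-fraction schedule back to the inflow concentration."""
    f = np.asarray(f, dtype=float)
    cin = chamber.buffer_conc_uM + f * (chamber.stim_conc_uM - chamber.buffer_conc_uM)
    return StimulusProfile(np.asarray(times, float), cin, meta={"kind": "inflow"})


def finite_derivatives(profile: StimulusProfile, window: int = 1) -> StimulusProfile:
    """Fill d1/d2 by central differences, optionally pre-smoothing.

    ``window`` is a moving-average width in samples applied to the
    concentration before differencing (1 = no smoothing).  Endpoints use
    one-sided differences (as provided by ``numpy.gradient``).
    """
    n = profile.times.size
    if n < 3:
        raise ParameterError("need at least 3 samples for finite derivatives")
    if window < 1 or window > n:
        raise ParameterError(f"window must be in [1, {n}]")
    conc = profile.conc
    if window > 1:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(conc, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="same")[pad : pad + n]
    else:
        smoothed = conc
    d1 = np.gradient(smoothed, profile.times)
    d2 = np.gradient(d1, profile.times)
    return StimulusProfile(profile.times, profile.conc, d1, d2, meta=dict(profile.meta))
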