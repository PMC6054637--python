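"""Agent-based chemotaxis: biased random walk vs first-derivative adaptation.

Agents walk at unit speed on a 2-D plane carrying a scalar attractant field.
Each step they sense the local concentration, form the temporal difference
``delta_c`` with the previous sample, and turn (resampling a uniformly random
heading) with probability ``p_plus`` when the decision signal is non-negative
and ``p_minus`` when it is negative.

*Classical* strategy: signal = delta_c — the textbook biased random walk that
uses only the sign of the concentration's first derivative.

*Adaptive* strategy: two sensory pathways shape the turn decision, mirroring
the AWA/AWC division of labour.  A robust, non-adapting pathway fires the
``p_minus`` turn rate whenever the concentration drops (delta_c < 0).  On
top of it, an adapting pathway keeps an exponential moving average (EMA) of
past delta_c values with memory ``M`` steps and compares the current sample
against it (signal = delta_c − EMA): a sustained derivative level is adapted
away, so a *rising* concentration whose rate of rise has stopped growing
also reads as "turn" (``p_minus``), re-sampling directions until the agent
finds a steeper, better target-directed path.  Only a rising concentration
that still beats the recent past — or the complete absence of detectable
signal — keeps the spontaneous ``p_plus`` rate.

Performance is the chemotaxis score: the mean projection of the unit step
velocity onto the instantaneous direct line to the source, in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ParameterError

__all__ = [
    "GradientField",
    "StrategyParams",
    "AgentState",
    "SimResult",
    "field_conc",
    "update_adaptation",
    "step_agent",
    "simulate_agents",
    "simulate_trajectory",
    "chemotaxis_score",
    "run_grid",
    "fold_improvement",
    "compare_strategies",
    "linear_drift_oracle",
    "simulate_linear_drift",
]

STRATEGIES = ("classical", "adaptive")


@dataclass(frozen=True)
class GradientField:
    """Spatial attractant field (units: step lengths, arbitrary concentration).

    ``gaussian``: C(p) = peak_conc * exp(-|p - source|^2 / (2 sigma^2)).
    ``linear``:   C(p) = max(0, offset + slope . p) with ``source`` ignored by
    the concentration but kept as the scoring target.
    """

    kind: str = "gaussian"
    source: tuple[float, float] = (0.0, 0.0)
    peak_conc: float = 1.0
    sigma: float = 50.0
    slope: tuple[float, float] = (1.0, 0.0)
    offset: float = 0.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "linear"):
            raise ParameterError(f"unknown field kind {self.kind!r}")
        if self.kind == "gaussian" and (self.peak_conc <= 0 or self.sigma <= 0):
            raise ParameterError("gaussian field needs peak_conc > 0 and sigma > 0")


def field_conc(fld: GradientField, x, y):
    """Concentration at position(s) (x, y); vectorised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fld.kind == "gaussian":
        dx = x - fld.source[0]
        dy = y - fld.source[1]
        return fld.peak_conc * np.exp(-(dx * dx + dy * dy) / (2.0 * fld.sigma**2))
    gx, gy = fld.slope
    return np.maximum(0.0, fld.offset + gx * x + gy * y)


@dataclass(frozen=True)
class StrategyParams:
    """Turning rule and run-length configuration for one simulated strategy.

    Defaults place the agent 200 step lengths (4 sigma) from a Gaussian
    source of width sigma = 50 and let it walk 2000 steps; a run ends early
    on entering the capture radius, set to one field width so that arrival
    precedes the flattening core where the derivative cue necessarily
    reverses.  ``memory`` is the adaptation EMA memory in steps (used only
    when ``adapt`` is true); ``sense_noise_sd`` is the SD of additive
    Gaussian noise on every concentration sample.

    ``sense_threshold`` is the sensor's detection floor: sampled
    concentrations below it read as zero.  The default equals the field
    concentration at the default start distance, i.e. the agent starts at the
    edge of the detectable plume; a walker that carries itself outside the
    plume receives no derivative signal at all (delta = 0, routed to the
    ``p_plus`` branch by the tie rule), so spontaneous reorientation is the
    only way back in.
    """

    p_plus: float = 0.1
    p_minus: float = 0.5
    adapt: bool = False
    memory: int = 50
    sense_noise_sd: float = 0.0
    sense_threshold: float = 3.3546262790251185e-04  # exp(-8): C at 4 sigma
    step_length: float = 1.0
    n_steps: int = 2000
    start_distance: float = 200.0
    capture_radius: float = 50.0

    def __post_init__(self):
        if not (0.0 <= self.p_plus <= 1.0 and 0.0 <= self.p_minus <= 1.0):
            raise ParameterError("turning probabilities must lie in [0, 1]")
        if self.memory < 1:
            raise ParameterError("memory must be >= 1 step")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")


@dataclass
class AgentState:
    """Single-agent state for the stepwise interface."""

    x: float
    y: float
    heading: float  # radians
    prev_sensed: float
    ema: float = 0.0


@dataclass
class SimResult:
    """Grid-scan output: per-cell mean chemotaxis scores for each strategy."""

    p_plus_grid: np.ndarray
    p_minus_grid: np.ndarray
    scores: dict  # strategy -> (len(p_minus_grid), len(p_plus_grid)) means
    capture_fraction: dict
    reps: int
    seed: int
    fld: GradientField = field(default_factory=GradientField)
    params: StrategyParams = field(default_factory=StrategyParams)


def update_adaptation(ema: float, delta_c: float, memory: int) -> tuple[float, float]:
    """One EMA adaptation update.

    Returns (new_ema, signal) with signal = delta_c - ema (the pre-update
    EMA) and new_ema = ema + (delta_c - ema) / memory.  A sustained constant
    delta_c drives the signal to zero (perfect adaptation); memory -> inf
    recovers the classical sign-of-derivative signal (for ema0 = 0).
    """
    if memory < 1:
        raise ParameterError("memory must be >= 1")
    signal = delta_c - ema
    return ema + signal / memory, signal


def step_agent(
    state: AgentState,
    strategy: StrategyParams,
    fld: GradientField,
    rng: np.random.Generator,
) -> AgentState:
    """Advance a single agent one step (reference scalar implementation).

    Sense -> temporal difference -> (optional) adaptation -> turn decision ->
    move one step length along the (possibly resampled) heading.  A signal of
    exactly zero counts as non-negative and uses ``p_plus``; so does the
    no-signal condition (nothing detectable now or on the previous sample),
    where neither pathway is driven and only spontaneous turning remains.
    """
    sensed = float(field_conc(fld, state.x, state.y))
    if strategy.sense_noise_sd > 0:
        sensed += strategy.sense_noise_sd * rng.standard_normal()
    if sensed < strategy.sense_threshold:
        sensed = 0.0
    delta_c = sensed - state.prev_sensed
    if strategy.adapt:
        ema, signal = update_adaptation(state.ema, delta_c, strategy.memory)
        no_signal = sensed == 0.0 and delta_c == 0.0
        up = delta_c >= 0 and (signal >= 0 or no_signal)
    else:
        ema, signal = state.ema, delta_c
        up = signal >= 0
    p = strategy.p_plus if up else strategy.p_minus
    u_turn = rng.random()
    u_head = rng.random()
    heading = 2.0 * np.pi * u_head if u_turn < p else state.heading
    return AgentState(
        x=state.x + strategy.step_length * np.cos(heading),
        y=state.y + strategy.step_length * np.sin(heading),
        heading=heading,
        prev_sensed=sensed,
        ema=ema,
    )


def _simulate_batch(
    n: int,
    strategy: StrategyParams,
    fld: GradientField,
    rng: np.random.Generator,
    drift_axis: tuple[float, float] | None = None,
):
    """Vectorised simulation of ``n`` independent agents.

    Returns (scores, captured, steps_to_capture) where scores are per-agent
    mean step projections onto the direct line to the source (or onto
    ``drift_axis`` when given, for linear-gradient drift measurements).

    The random stream is consumed identically regardless of ``adapt``, so
    classical and adaptive runs from the same substream see matched draws.
    """
    sx, sy = fld.source
    L = strategy.step_length
    x = np.full(n, sx + strategy.start_distance)
    y = np.full(n, sy, dtype=float)
    heading = 2.0 * np.pi * rng.random(n)
    sensed0 = np.asarray(field_conc(fld, x, y), dtype=float).copy()
    if strategy.sense_noise_sd > 0:
        sensed0 += strategy.sense_noise_sd * rng.standard_normal(n)
    prev = np.where(sensed0 >= strategy.sense_threshold, sensed0, 0.0)
    ema = np.zeros(n)
    score_sum = np.zeros(n)
    score_cnt = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    steps_to_capture = np.full(n, -1, dtype=np.int64)
    inv_m = 1.0 / strategy.memory
    capture = strategy.capture_radius > 0
    if drift_axis is not None:
        ax, ay = drift_axis

    for step in range(strategy.n_steps):
        sensed = np.asarray(field_conc(fld, x, y), dtype=float)
        if strategy.sense_noise_sd > 0:
            sensed = sensed + strategy.sense_noise_sd * rng.standard_normal(n)
        sensed = np.where(sensed >= strategy.sense_threshold, sensed, 0.0)
        delta = sensed - prev
        if strategy.adapt:
            signal = delta - ema
            ema = np.where(active, ema + signal * inv_m, ema)
            no_signal = (sensed == 0.0) & (delta == 0.0)
            up = (delta >= 0.0) & ((signal >= 0.0) | no_signal)
        else:
            up = delta >= 0.0
        p = np.where(up, strategy.p_plus, strategy.p_minus)
        u_turn = rng.random(n)
        u_head = rng.random(n)
        turn = (u_turn < p) & active
        heading = np.where(turn, 2.0 * np.pi * u_head, heading)
        dxs = np.cos(heading)
        dys = np.sin(heading)
        if drift_axis is None:
            tx = sx - x
            ty = sy - y
            dist = np.hypot(tx, ty)
            with np.errstate(invalid="ignore", divide="ignore"):
                proj = (dxs * tx + dys * ty) / dist
            proj = np.where(dist > 0, proj, 0.0)
        else:
            proj = dxs * ax + dys * ay
        score_sum += np.where(active, proj, 0.0)
        score_cnt += active
        x = np.where(active, x + L * dxs, x)
        y = np.where(active, y + L * dys, y)
        prev = np.where(active, sensed, prev)
        if capture:
            d2 = (sx - x) ** 2 + (sy - y) ** 2
            newly = active & (d2 <= strategy.capture_radius**2)
            steps_to_capture[newly] = step + 1
            active &= ~newly
            if not active.any():
                break
    scores = score_sum / np.maximum(score_cnt, 1)
    return scores, steps_to_capture >= 0, steps_to_capture


def simulate_agents(
    strategy: StrategyParams,
    fld: GradientField,
    n_runs: int,
    seed: int | np.random.SeedSequence = 0,
):
    """Run ``n_runs`` independent agents; returns (scores, captured, steps)."""
    rng = np.random.default_rng(seed)
    return _simulate_batch(n_runs, strategy, fld, rng)


def simulate_trajectory(
    strategy: StrategyParams,
    fld: GradientField,
    seed: int = 0,
) -> np.ndarray:
    """Positions (n_steps+1, 2) of one agent, via the scalar reference stepper."""
    rng = np.random.default_rng(seed)
    state = AgentState(
        x=fld.source[0] + strategy.start_distance,
        y=fld.source[1],
        heading=float(2.0 * np.pi * rng.random()),
        prev_sensed=float(field_conc(fld, fld.source[0] + strategy.start_distance, fld.source[1])),
    )
    pos = [(state.x, state.y)]
    for _ in range(strategy.n_steps):
        state = step_agent(state, strategy, fld, rng)
        pos.append((state.x, state.y))
        if (
            strategy.capture_radius > 0
            and np.hypot(state.x - fld.source[0], state.y - fld.source[1])
            <= strategy.capture_radius
        ):
            break
    return np.asarray(pos)


def chemotaxis_score(positions: np.ndarray, source: tuple[float, float]) -> float:
    """Mean projection of step velocity onto the direct line to the source.

    ``positions`` is an (n, 2) array of a trajectory (post-capture samples
    should already be trimmed).  Zero-displacement steps are excluded.
    Returns a value in [-1, 1].
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise ParameterError("need an (n>=2, 2) position array")
    steps = np.diff(pos, axis=0)
    norms = np.hypot(steps[:, 0], steps[:, 1])
    tx = source[0] - pos[:-1, 0]
    ty = source[1] - pos[:-1, 1]
    dist = np.hypot(tx, ty)
    ok = (norms > 0) & (dist > 0)
    if not ok.any():
        raise ParameterError("all steps have zero displacement")
    proj = (steps[ok, 0] * tx[ok] + steps[ok, 1] * ty[ok]) / (norms[ok] * dist[ok])
    return float(proj.mean())


def _cell_seed(seed: int, i: int, j: int) -> np.random.SeedSequence:
    # deterministic, order-independent substream per grid cell; the same
    # substream is replayed for both strategies so their draws are matched
    return np.random.SeedSequence(entropy=seed, spawn_key=(i, j))


def run_grid(
    p_plus_grid: Iterable[float],
    p_minus_grid: Iterable[float],
    reps: int = 800,
    strategies: tuple[str, ...] = STRATEGIES,
    fld: GradientField | None = None,
    seed: int = 0,
    params: StrategyParams | None = None,
) -> SimResult:
    """Scan the (p_plus, p_minus) grid for each strategy.

    Every cell uses its own RNG substream derived from (seed, row, column),
    replayed identically for each strategy, so results are bitwise
    reproducible and independent of execution order.  ``scores[s][i, j]`` is
    the mean chemotaxis score over ``reps`` runs at p_minus = row i,
    p_plus = column j.
    """
    fld = fld or GradientField()
    base = params or StrategyParams()
    pp = np.asarray(list(p_plus_grid), dtype=float)
    pm = np.asarray(list(p_minus_grid), dtype=float)
    if np.any((pp < 0) | (pp > 1)) or np.any((pm < 0) | (pm > 1)):
        raise ParameterError("grid probabilities must lie in [0, 1]")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    for s in strategies:
        if s not in STRATEGIES:
            raise ParameterError(f"unknown strategy {s!r}")
    scores = {s: np.empty((pm.size, pp.size)) for s in strategies}
    capfrac = {s: np.empty((pm.size, pp.size)) for s in strategies}
    for i, pmv in enumerate(pm):
        for j, ppv in enumerate(pp):
            ss = _cell_seed(seed, i, j)
            for s in strategies:
                cfg = replace(base, p_plus=float(ppv), p_minus=float(pmv), adapt=(s == "adaptive"))
                rng = np.random.default_rng(ss)
                sc, captured, _ = _simulate_batch(reps, cfg, fld, rng)
                scores[s][i, j] = sc.mean()
                capfrac[s][i, j] = captured.mean()
    return SimResult(
        p_plus_grid=pp,
        p_minus_grid=pm,
        scores=scores,
        capture_fraction=capfrac,
        reps=reps,
        seed=seed,
        fld=fld,
        params=base,
    )


def fold_improvement(
    adapt_grid: np.ndarray, classic_grid: np.ndarray, eps: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Percent improvement of the adaptive over the classical strategy per cell.

        100 * (adaptive - classical) / classical

    Cells where |classical| <= eps are masked (the ratio blows up near the
    p_plus = p_minus diagonal where the classical walker cannot navigate).

    Returns (matrix, mask); masked entries are NaN in the matrix.
    """
    a = np.asarray(adapt_grid, dtype=float)
    c = np.asarray(classic_grid, dtype=float)
    if a.shape != c.shape:
        raise ParameterError("grids must have the same shape")
    mask = np.abs(c) <= eps
    out = np.full_like(a, np.nan)
    np.divide(100.0 * (a - c), c, out=out, where=~mask)
    return out, mask


def compare_strategies(adapt_grid: np.ndarray, classic_grid: np.ndarray):
    """One-sided Wilcoxon signed-rank test that adaptive > classical over cells.

    Pairs are the per-cell mean scores; returns (statistic, p).
    """
    from .adaptation import wilcoxon_test

    a = np.asarray(adapt_grid, dtype=float).ravel()
    c = np.asarray(classic_grid, dtype=float).ravel()
    if a.size < 6:
        raise ParameterError("need at least 6 paired cells")
    return wilcoxon_test(a, c, mode="signed_rank_paired", side="greater")


def linear_drift_oracle(p_plus: float, p_minus: float) -> float:
    """Stationary per-step drift (units of step length) up a linear gradient.

    For the classical strategy in a noiseless linear field, the heading is a
    renewal process: a heading theta persists for a geometric number of steps
    with mean 1/p(theta), where p(theta) = p_plus if cos(theta) >= 0 else
    p_minus, and new headings are uniform.  The stationary heading density is
    therefore proportional to 1/p(theta), giving

        drift = E[cos theta] = 2 (p_minus - p_plus) / (pi (p_plus + p_minus)).

    The limit p_plus -> 0 gives 2/pi (absorption into an up-gradient heading,
    uniform on (-pi/2, pi/2)); p_plus = p_minus gives zero drift.
    """
    if not (0 <= p_plus <= 1 and 0 <= p_minus <= 1):
        raise ParameterError("probabilities must lie in [0, 1]")
    if p_plus == 0 and p_minus == 0:
        return 0.0  # no turns ever: initial uniform heading, zero mean drift
    return 2.0 * (p_minus - p_plus) / (np.pi * (p_plus + p_minus))


def simulate_linear_drift(
    p_plus: float,
    p_minus: float,
    n_runs: int = 100,
    n_steps: int = 1000,
    seed: int = 0,
    slope: float = 1.0,
) -> np.ndarray:
    """Per-run mean drift along a linear gradient for the classical strategy.

    Uses a large offset so the clipped linear field stays strictly positive
    over the walk, matching the oracle's unbounded-gradient assumption.
    """
    offset = 10.0 * slope * n_steps  # keep C > 0 everywhere reachable
    fld = GradientField(kind="linear", slope=(slope, 0.0), offset=offset, source=(0.0, 0.0))
    cfg = StrategyParams(
        p_plus=p_plus,
        p_minus=p_minus,
        adapt=False,
        n_steps=n_steps,
        start_distance=0.0,
        capture_radius=0.0,
    )
    rng = np.random.default_rng(seed)
    drifts, _, _ = _simulate_batch(n_runs, cfg, fld, rng, drift_axis=(1.0, 0.0))
    return drifts
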