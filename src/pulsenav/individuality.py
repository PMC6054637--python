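"""Pulse-individuality shuffle (bootstrap) test.

Each animal emits calcium pulses with a characteristic signature: its pulses'
amplitudes and decay times cluster more tightly than pulses pooled across
animals.  The test statistic is the mean over worms of the within-worm sample
standard deviation of a pulse parameter.  The null distribution is built by
shuffling all pulses between worms while preserving each worm's pulse count;
individuality shows up as the observed statistic sitting in the LOW tail of
the shuffled distribution (one-sided), because shuffling mixes dissimilar
pulses into every worm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = ["ShuffleTestResult", "mean_within_worm_sd", "shuffle_individuality_test"]

_PARAM_COLUMNS = {
    "amplitude": "amplitude",
    "tau": "tau_s",
    "peak_to_peak": "interval_s",
}


@dataclass(frozen=True)
class ShuffleTestResult:
    """Outcome of the individuality shuffle test for one pulse parameter."""

    parameter: str
    observed_mean_sd: float
    null_mean_sds: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int

    def summary(self) -> dict:
        q = np.quantile(self.null_mean_sds, [0.025, 0.5, 0.975])
        return {
            "parameter": self.parameter,
            "observed_mean_sd": self.observed_mean_sd,
            "null_q025": float(q[0]),
            "null_median": float(q[1]),
            "null_q975": float(q[2]),
            "p_value": self.p_value,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }


def _eligible_values(pulse_table: pd.DataFrame, parameter: str):
    """Values and per-worm counts after dropping worms with < 2 pulses."""
    col = _PARAM_COLUMNS.get(parameter, parameter)
    if col not in pulse_table.columns:
        raise DataError(f"pulse table lacks column {col!r} for parameter {parameter!r}")
    tab = pulse_table[["worm_id", col]].dropna()
    counts = tab.groupby("worm_id").size()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(
            f"excluding {len(small)} worm(s) with <2 pulses: {sorted(map(str, small))}",
            stacklevel=3,
        )
        tab = tab[~tab["worm_id"].isin(small)]
    if tab["worm_id"].nunique() < 2:
        raise DataError("need at least 2 worms with >= 2 pulses each")
    tab = tab.sort_values("worm_id", kind="stable")
    values = tab[col].to_numpy(dtype=float)
    sizes = tab.groupby("worm_id", sort=True).size().to_numpy()
    return values, sizes


def _segment_mean_sd(values_2d: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Mean over contiguous segments of the sample SD (ddof=1), vectorised.

    ``values_2d`` has shape (n_datasets, n_pulses); segments along axis 1 are
    given by ``sizes``.
    """
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    sums = np.add.reduceat(values_2d, starts, axis=1)
    sqs = np.add.reduceat(values_2d**2, starts, axis=1)
    n = sizes[np.newaxis, :]
    var = (sqs - sums**2 / n) / (n - 1)
    return np.sqrt(np.maximum(var, 0.0)).mean(axis=1)


def mean_within_worm_sd(pulse_table: pd.DataFrame, parameter: str) -> float:
    """Mean over worms of the within-worm sample SD (n-1 denominator).

    Worms with fewer than two pulses are excluded with a warning; an error is
    raised if fewer than two eligible worms remain.
    """
    values, sizes = _eligible_values(pulse_table, parameter)
    return float(_segment_mean_sd(values[np.newaxis, :], sizes)[0])


def shuffle_individuality_test(
    pulse_table: pd.DataFrame,
    parameter: str,
    n_shuffles: int = 10_000,
    seed: int = 0,
    batch: int = 2_000,
) -> ShuffleTestResult:
    """Shuffle test for worm individuality in one pulse parameter.

    All pulses are randomly reassigned between worms (each worm keeps its
    original pulse count) ``n_shuffles`` times; the statistic
    :func:`mean_within_worm_sd` is recomputed for each shuffle.  The one-sided
    p-value for the observed statistic being LOW uses the add-one correction

        p = (1 + #{null <= observed}) / (n_shuffles + 1)

    so it is never exactly zero.

    Deterministic given (data, n_shuffles, seed).
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    values, sizes = _eligible_values(pulse_table, parameter)
    observed = float(_segment_mean_sd(values[np.newaxis, :], sizes)[0])
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_shuffles)
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        # one permutation per row via argsort of iid uniforms
        order = np.argsort(rng.random((b, values.size)), axis=1)
        nulls[done : done + b] = _segment_mean_sd(values[order], sizes)
        done += b
    p = (1.0 + np.count_nonzero(nulls <= observed)) / (n_shuffles + 1.0)
    return ShuffleTestResult(
        parameter=parameter,
        observed_mean_sd=observed,
        null_mean_sds=nulls,
        p_value=float(p),
        n_shuffles=n_shuffles,
        seed=seed,
    )
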