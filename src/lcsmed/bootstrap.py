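"""Bias-corrected (BC) bootstrap confidence intervals.

Participants (whole rows) are resampled with replacement, the statistic
is recomputed per draw, and the percentile endpoints are shifted by the
bias constant z0 = Phi^{-1}(fraction of draws below the full-sample
statistic).  Draws exactly equal to the point estimate count half below
(mid-p convention); a fraction of 0 or 1 is clamped to 1/(draws + 1) from
the boundary so z0 stays finite.  No acceleration constant is applied
(BC, not BCa).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BootstrapInterval", "BootstrapError", "bc_interval_from_draws", "bc_bootstrap_ci"]


class BootstrapError(RuntimeError):
    pass


@dataclass(frozen=True)
class BootstrapInterval:
    low: float
    high: float
    level: float
    draws: int
    z0: float
    seed: int | None = None
    n_failed: int = 0

    def __contains__(self, value: float) -> bool:
        return self.low <= value <= self.high


def bc_interval_from_draws(
    draw_values: np.ndarray,
    point: float,
    level: float = 0.95,
    seed: int | None = None,
    n_failed: int = 0,
) -> BootstrapInterval:
    """BC interval endpoints from an array of bootstrap statistics."""
    v = np.asarray(draw_values, float)
    v = v[np.isfinite(v)]
    m = len(v)
    if m == 0:
        raise BootstrapError("no successful bootstrap draws")
    frac = (np.sum(v < point) + 0.5 * np.sum(v == point)) / m
    lo_clamp, hi_clamp = 1.0 / (m + 1), m / (m + 1.0)
    if frac < lo_clamp or frac > hi_clamp:
        warnings.warn(
            "bootstrap distribution entirely on one side of the point estimate; "
            "bias constant clamped",
            stacklevel=2,
        )
        frac = min(max(frac, lo_clamp), hi_clamp)
    z0 = float(stats.norm.ppf(frac))
    alpha = 1.0 - level
    q_lo = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
    q_hi = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
    return BootstrapInterval(
        low=float(np.quantile(v, q_lo)),
        high=float(np.quantile(v, q_hi)),
        level=level,
        draws=m,
        z0=z0,
        seed=seed,
        n_failed=n_failed,
    )


def bc_bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    draws: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapInterval:
    """BC bootstrap interval for an arbitrary statistic of a trial table.

    ``statistic`` is evaluated on the full table for the point estimate
    and on ``draws`` row-resampled tables.  Draws where the statistic
    raises (e.g. a singular refit) are dropped and counted in
    ``n_failed``; if every draw fails a :class:`BootstrapError` is raised.
    Identical ``(seed, draws)`` give an identical interval.
    """
    if draws < 1:
        raise BootstrapError("draws must be >= 1")
    point = float(statistic(table))
    rng = np.random.default_rng(seed)
    n = len(table)
    values = []
    n_failed = 0
    for _ in range(draws):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(statistic(table.iloc[idx])))
        except Exception:
            n_failed += 1
    if not values:
        raise BootstrapError("all bootstrap draws failed")
    return bc_interval_from_draws(
        np.asarray(values), point, level=level, seed=seed, n_failed=n_failed
    )
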