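"""Self-validation studies: estimator/oracle equivalence, ground-truth
parameter recovery, bootstrap interval coverage, and randomization
balance.  These are the package's own quality gates, run by the test
suite and the acceptance script."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .mediation import MultiMediatorLCS, SingleMediatorLCS
from .lcs import LatentChangeScoreModel
from .simulate import MEDIATORS, SimulationConfig, generate_trial, stratified_block_randomize

__all__ = [
    "lcs_vs_ols_max_gap",
    "recovery_study",
    "coverage_study",
    "randomization_balance_study",
]


def _normal_equation_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # explicit normal-equations solution, independent of the engine's SVD path
    return np.linalg.solve(X.T @ X, X.T @ y)


def lcs_vs_ols_max_gap(n_fixtures: int = 20, n: int = 80, seed: int = 0) -> float:
    """Max |difference| between change-model estimates and explicit
    normal-equations least squares on observed difference scores, over
    random complete-data fixtures.

    With unit-fixed loadings the two are the same estimator, so the gap
    is pure floating-point noise.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        arm = rng.integers(0, 2, n)
        waves = [rng.normal(30, 8, n)]
        for _w in range(3):
            waves.append(waves[-1] + rng.normal(-4, 5, n) + arm * rng.normal(-3, 1))
        table = pd.DataFrame({"arm": arm} | {f"bdi_{w}": waves[w] for w in range(4)})
        model = LatentChangeScoreModel().fit(table)

        tc = arm - arm.mean()
        base_mean = waves[0].mean()
        levels = [w - base_mean for w in waves[:3]]
        ones = np.ones(n)
        designs = [
            (levels[0], np.column_stack([ones, tc])),
            (waves[1] - waves[0], np.column_stack([ones, tc, levels[0]])),
            (waves[2] - waves[1], np.column_stack([ones, tc, levels[1], levels[0]])),
            (waves[3] - waves[2], np.column_stack([ones, tc, levels[2], levels[0]])),
        ]
        for eq, (y, X) in zip(model.equations_, designs):
            ref = _normal_equation_fit(X, y)
            got = np.array([e.estimate for e in eq.estimates])
            worst = max(worst, float(np.max(np.abs(got - ref))))
    return worst


def recovery_study(
    n_trials: int = 100, n_participants: int = 103, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Fit the simultaneous mediation model on repeated default-parameter
    trials and compare mean fitted paths with the generative truth.

    Returns per path: truth, mean estimate, Monte-Carlo SE of the mean,
    and the standardized deviation ``z = |mean - truth| / mc_se``.
    """
    rows = []
    for r in range(n_trials):
        cfg = SimulationConfig(
            n_participants=n_participants, seed=(seed * 100_003 + r) % 2**31
        )
        table, truth = generate_trial(cfg)
        fit = MultiMediatorLCS(n_boot=0, mediator_window=(0, 3)).fit(table)
        row = {f"a_{m}": fit.a_[m].estimate for m in MEDIATORS}
        row |= {f"b_{m}": fit.b_[m].estimate for m in MEDIATORS}
        row["c_prime"] = fit.c_prime_.estimate
        rows.append(row)
    frame = pd.DataFrame(rows)
    truth_map = {f"a_{m}": truth["a"][m] for m in MEDIATORS}
    truth_map |= {f"b_{m}": truth["b"][m] for m in MEDIATORS}
    truth_map["c_prime"] = truth["c_prime"]
    out = {}
    for path, t in truth_map.items():
        mean = float(frame[path].mean())
        mc_se = float(frame[path].std(ddof=1) / np.sqrt(n_trials))
        out[path] = {
            "truth": t,
            "mean": mean,
            "mc_se": mc_se,
            "z": abs(mean - t) / mc_se,
        }
    return out


def coverage_study(
    n_trials: int = 500,
    draws: int = 999,
    n_participants: int = 103,
    mediator: str = "bads",
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical coverage of the bias-corrected bootstrap interval for a
    nonzero indirect effect across simulated trials."""
    hits = 0
    for r in range(n_trials):
        cfg = SimulationConfig(
            n_participants=n_participants, seed=(seed * 99_991 + r) % 2**31
        )
        table, truth = generate_trial(cfg)
        fit = SingleMediatorLCS(
            mediator=mediator, n_boot=draws, level=level,
            seed=(seed * 7 + r) % 2**31,
        ).fit(table)
        bi = fit.bootstrap_[mediator]
        hits += bi.low <= truth["indirect"][mediator] <= bi.high
    coverage = hits / n_trials
    return {
        "coverage": coverage,
        "n_trials": n_trials,
        "draws": draws,
        "nominal": level,
        "binomial_se": float(np.sqrt(level * (1 - level) / n_trials)),
    }


def randomization_balance_study(
    n_inputs: int = 1000, block_size: int = 10, seed: int = 0
) -> dict[str, float]:
    """Check the permuted-block guarantees across random inputs.

    Every complete block within a stratum must split exactly evenly, and
    total imbalance can never exceed (number of strata) x block_size / 2.
    """
    rng = np.random.default_rng(seed)
    even_blocks = True
    max_imbalance_ratio = 0.0
    for r in range(n_inputs):
        n = int(rng.integers(1, 120))
        n_strata = int(rng.integers(1, 4))
        labels = rng.integers(0, n_strata, n).astype(str)
        arms = stratified_block_randomize(labels, block_size, seed=int(rng.integers(2**31)))
        for s in np.unique(labels):
            idx = np.flatnonzero(labels == s)
            for b0 in range(0, len(idx) - block_size + 1, block_size):
                block = arms[idx[b0: b0 + block_size]]
                if block.sum() != block_size // 2:
                    even_blocks = False
        bound = len(np.unique(labels)) * block_size / 2
        max_imbalance_ratio = max(
            max_imbalance_ratio, abs(2 * arms.sum() - n) / bound
        )
    return {
        "n_inputs": n_inputs,
        "all_complete_blocks_even": float(even_blocks),
        "max_imbalance_over_bound": max_imbalance_ratio,
    }
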