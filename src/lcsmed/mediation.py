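"""Single- and multi-mediator latent change score mediation.

The mediation system regresses (1) each mediator's wave-window change on
centered treatment plus baseline covariates — the *a* path — and (2) the
outcome's change on the mediator change(s) — the *b* path(s) — plus
centered treatment — the direct effect *c'* — and the same baselines.
The indirect effect per mediator is a*b, the combined indirect is the sum
over mediators, the total effect is combined indirect + c', and percent
mediated is 100 * indirect / total.  Indirect effects are tested with
bias-corrected bootstrap intervals over participant resamples.

Default change windows follow the trial being emulated: baseline to
3 months for both mediator and outcome in single-mediator models;
baseline to 2 months for mediators and baseline to 3 months for the
outcome when all mediators enter simultaneously.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bootstrap import BootstrapInterval, bc_interval_from_draws
from .lcs import (
    ChangeScoreSpec,
    EquationFit,
    LcsError,
    PathEstimate,
    compute_change_scores,
    fit_equation,
)

__all__ = [
    "MediationSpec",
    "MediationResult",
    "indirect_summary",
    "SingleMediatorLCS",
    "MultiMediatorLCS",
    "fit_single_mediator",
    "fit_multiple_mediator",
]


def indirect_summary(
    a: float, b: float, c_prime: float
) -> tuple[float, float, float]:
    """Indirect, total and percent-mediated from path estimates.

    indirect = a * b; total = indirect + c'; percent = 100 * indirect /
    total.  When the total is exactly zero the percent is returned as NaN
    (flagged, not raised) so batch summaries keep flowing.
    """
    indirect = a * b
    total = indirect + c_prime
    percent = np.nan if total == 0 else 100.0 * indirect / total
    return indirect, total, percent


@dataclass(frozen=True)
class MediationSpec:
    """Declarative description of a mediation analysis."""

    mediators: tuple[str, ...]
    mediator_window: tuple[int, int] = (0, 3)
    outcome_window: tuple[int, int] = (0, 3)
    level: float = 0.95
    draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for f, t in (self.mediator_window, self.outcome_window):
            if f >= t:
                raise LcsError("change windows must run forward in time")
        if self.draws < 1:
            raise LcsError("bootstrap draws must be >= 1")
        if not 0 < self.level < 1:
            raise LcsError("CI level must be in (0, 1)")


@dataclass
class MediationResult:
    """Paths, indirect effects and bootstrap intervals of one model."""

    mediators: list[str]
    a: dict[str, PathEstimate]
    b: dict[str, PathEstimate]
    c_prime: PathEstimate
    indirect: dict[str, float]
    combined_indirect: float
    total: float
    percent_mediated: dict[str, float]
    percent_combined: float
    bootstrap: dict[str, BootstrapInterval] = field(default_factory=dict)
    equations: list[EquationFit] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Report with path rows and summary rows (indirect, total,
        percent mediated, bootstrap CI)."""
        rows = []
        for m in self.mediators:
            for tag, est in (("a", self.a[m]), ("b", self.b[m])):
                rows.append(
                    {
                        "term": f"{tag}[{m}]",
                        "estimate": est.estimate,
                        "se": est.se,
                        "z": est.z,
                        "p": est.p,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
        e = self.c_prime
        rows.append(
            {
                "term": "c_prime",
                "estimate": e.estimate,
                "se": e.se,
                "z": e.z,
                "p": e.p,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
        )
        for m in self.mediators:
            bi = self.bootstrap.get(m)
            rows.append(
                {
                    "term": f"indirect[{m}]",
                    "estimate": self.indirect[m],
                    "ci_low": bi.low if bi else np.nan,
                    "ci_high": bi.high if bi else np.nan,
                }
            )
        bi = self.bootstrap.get("combined")
        rows.append(
            {
                "term": "indirect[combined]",
                "estimate": self.combined_indirect,
                "ci_low": bi.low if bi else np.nan,
                "ci_high": bi.high if bi else np.nan,
            }
        )
        rows.append({"term": "total", "estimate": self.total})
        for m in self.mediators:
            rows.append({"term": f"percent_mediated[{m}]", "estimate": self.percent_mediated[m]})
        rows.append({"term": "percent_mediated[combined]", "estimate": self.percent_combined})
        return pd.DataFrame(rows)


class _MediationBase(BaseEstimator):
    """Shared machinery for the mediation estimators."""

    def _mediator_list(self) -> list[str]:
        raise NotImplementedError

    def _windows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return tuple(self.mediator_window), tuple(self.outcome_window)

    def _working(self, X: pd.DataFrame) -> tuple[pd.DataFrame, list[str], str]:
        meds = self._mediator_list()
        mwin, owin = self._windows()
        out = self.outcome
        needed = ["arm", f"{out}_{owin[0]}", f"{out}_{owin[1]}"]
        for m in meds:
            needed += [f"{m}_{mwin[0]}", f"{m}_{mwin[1]}"]
        for col in needed:
            if col not in X.columns:
                raise LcsError(f"required column {col!r} missing from table")
        work = X.copy()
        work["treatment"] = work["arm"] - work["arm"].mean()
        dm_cols = []
        for m in meds:
            spec = ChangeScoreSpec(m, *mwin)
            work[spec.name] = compute_change_scores(work, spec)
            dm_cols.append(spec.name)
            work[f"{m}_base"] = work[f"{m}_{mwin[0]}"] - work[f"{m}_{mwin[0]}"].mean()
        ospec = ChangeScoreSpec(out, *owin)
        work[ospec.name] = compute_change_scores(work, ospec)
        work[f"{out}_base"] = work[f"{out}_{owin[0]}"] - work[f"{out}_{owin[0]}"].mean()
        return work, dm_cols, ospec.name

    def _fit_system(self, X: pd.DataFrame) -> None:
        meds = self._mediator_list()
        work, dm_cols, dy_col = self._working(X)
        out = self.outcome
        kw = dict(se_method=self.se_method, missing=self.missing, level=self.level)

        equations: list[EquationFit] = []
        a_paths: dict[str, PathEstimate] = {}
        for m, dm in zip(meds, dm_cols):
            eq = fit_equation(work, dm, ["treatment", f"{m}_base", f"{out}_base"], **kw)
            a_paths[m] = eq["treatment"]
            equations.append(eq)

        outcome_predictors = dm_cols + ["treatment"] + [f"{m}_base" for m in meds] + [f"{out}_base"]
        eq_out = fit_equation(work, dy_col, outcome_predictors, **kw)
        equations.append(eq_out)
        b_paths = {m: eq_out[dm] for m, dm in zip(meds, dm_cols)}
        c_prime = eq_out["treatment"]

        indirect = {m: a_paths[m].estimate * b_paths[m].estimate for m in meds}
        combined = float(sum(indirect.values()))
        total = combined + c_prime.estimate
        percent = {
            m: (np.nan if total == 0 else 100.0 * indirect[m] / total) for m in meds
        }
        percent_combined = np.nan if total == 0 else 100.0 * combined / total

        bootstrap = self._bootstrap_indirects(work, meds, dm_cols, dy_col, indirect, combined)

        self.result_ = MediationResult(
            mediators=list(meds),
            a=a_paths,
            b=b_paths,
            c_prime=c_prime,
            indirect=indirect,
            combined_indirect=combined,
            total=total,
            percent_mediated=percent,
            percent_combined=percent_combined,
            bootstrap=bootstrap,
            equations=equations,
        )
        self.a_ = a_paths
        self.b_ = b_paths
        self.c_prime_ = c_prime
        self.indirect_ = indirect
        self.combined_indirect_ = combined
        self.total_ = total
        self.percent_mediated_ = percent
        self.percent_combined_ = percent_combined
        self.bootstrap_ = bootstrap
        self.n_ = len(X)

    # -- fast batched bootstrap over participant resamples --------------
    def _bootstrap_indirects(
        self,
        work: pd.DataFrame,
        meds: Sequence[str],
        dm_cols: Sequence[str],
        dy_col: str,
        indirect: dict[str, float],
        combined: float,
    ) -> dict[str, BootstrapInterval]:
        if not self.n_boot:
            return {}
        out = self.outcome
        used = list(dm_cols) + [dy_col, "arm"] + [f"{m}_base" for m in meds] + [f"{out}_base"]
        rows = work.dropna(subset=used)
        n = len(rows)
        arm = rows["arm"].to_numpy(float)
        mbase = {m: rows[f"{m}_base"].to_numpy(float) for m in meds}
        ybase = rows[f"{out}_base"].to_numpy(float)
        dm = {m: rows[c].to_numpy(float) for m, c in zip(meds, dm_cols)}
        dy = rows[dy_col].to_numpy(float)

        # slope estimates are centering-invariant, so raw covariates are
        # used and only slopes are read out of each resampled fit
        Xa = {
            m: np.column_stack([np.ones(n), arm, mbase[m], ybase]) for m in meds
        }
        Xo = np.column_stack(
            [np.ones(n)] + [dm[m] for m in meds] + [arm] + [mbase[m] for m in meds] + [ybase]
        )

        rng = np.random.default_rng(self.seed)
        draws = int(self.n_boot)
        values = {m: [] for m in meds}
        n_failed = 0
        chunk = 2000
        done = 0
        while done < draws:
            k = min(chunk, draws - done)
            if self.stratify_by_arm:
                idx = np.empty((k, n), dtype=int)
                for g in (0, 1):
                    gi = np.flatnonzero(arm == g)
                    idx[:, gi] = gi[rng.integers(0, len(gi), size=(k, len(gi)))]
            else:
                idx = rng.integers(0, n, size=(k, n))
            try:
                a_sl = {}
                for m in meds:
                    Xb = Xa[m][idx]
                    yb = dm[m][idx]
                    beta = np.linalg.solve(
                        np.einsum("dnp,dnq->dpq", Xb, Xb),
                        np.einsum("dnp,dn->dp", Xb, yb)[..., None],
                    )[..., 0]
                    a_sl[m] = beta[:, 1]
                Xb = Xo[idx]
                yb = dy[idx]
                beta = np.linalg.solve(
                    np.einsum("dnp,dnq->dpq", Xb, Xb),
                    np.einsum("dnp,dn->dp", Xb, yb)[..., None],
                )[..., 0]
                for i, m in enumerate(meds):
                    values[m].append(a_sl[m] * beta[:, 1 + i])
            except np.linalg.LinAlgError:
                # rare singular resample: fall back to one-at-a-time fits
                for row_idx in idx:
                    try:
                        draw_vals = []
                        bo = np.linalg.lstsq(Xo[row_idx], dy[row_idx], rcond=None)[0]
                        for i, m in enumerate(meds):
                            ba = np.linalg.lstsq(Xa[m][row_idx], dm[m][row_idx], rcond=None)[0]
                            draw_vals.append(ba[1] * bo[1 + i])
                    except np.linalg.LinAlgError:
                        n_failed += 1
                        continue
                    for m, v in zip(meds, draw_vals):
                        values[m].append(np.atleast_1d(v))
            done += k

        arr = {m: np.concatenate(values[m]) for m in meds}
        result = {
            m: bc_interval_from_draws(
                arr[m], indirect[m], level=self.level, seed=self.seed, n_failed=n_failed
            )
            for m in meds
        }
        comb = np.sum([arr[m] for m in meds], axis=0)
        result["combined"] = bc_interval_from_draws(
            comb, combined, level=self.level, seed=self.seed, n_failed=n_failed
        )
        return result


class SingleMediatorLCS(_MediationBase):
    """Single-mediator LCS mediation model.

    The mediator's change over ``mediator_window`` is regressed on
    centered treatment plus baseline mediator and baseline outcome levels
    (the *a* path); the outcome change over ``outcome_window`` is
    regressed on the mediator change (*b*), centered treatment (*c'*) and
    the same baselines.  The indirect effect a*b receives a bias-corrected
    bootstrap interval over ``n_boot`` participant resamples.

    Attributes after ``fit`` include ``a_``, ``b_``, ``c_prime_``
    (:class:`~lcsmed.lcs.PathEstimate` keyed by mediator where relevant),
    ``indirect_``, ``total_``, ``percent_mediated_``, ``bootstrap_`` and
    the full ``result_``.
    """

    def __init__(
        self,
        mediator: str = "bads",
        outcome: str = "bdi",
        mediator_window: tuple[int, int] = (0, 3),
        outcome_window: tuple[int, int] = (0, 3),
        se_method: str = "ml",
        missing: str = "listwise",
        level: float = 0.95,
        n_boot: int = 10_000,
        seed: int = 0,
        stratify_by_arm: bool = False,
    ):
        self.mediator = mediator
        self.outcome = outcome
        self.mediator_window = mediator_window
        self.outcome_window = outcome_window
        self.se_method = se_method
        self.missing = missing
        self.level = level
        self.n_boot = n_boot
        self.seed = seed
        self.stratify_by_arm = stratify_by_arm

    def _mediator_list(self) -> list[str]:
        return [self.mediator]

    def fit(self, X: pd.DataFrame, y=None) -> "SingleMediatorLCS":
        self._fit_system(X)
        return self


class MultiMediatorLCS(_MediationBase):
    """Simultaneous multi-mediator LCS mediation model.

    One *a*-equation per mediator and a single outcome equation holding
    every mediator change, treatment and all baselines.  Independent
    indirect effects are a_i * b_i; the combined indirect is their sum.
    Default windows: mediator changes baseline -> 2 months, outcome
    change baseline -> 3 months.
    """

    def __init__(
        self,
        mediators: Sequence[str] = ("bads", "cds", "ptq"),
        outcome: str = "bdi",
        mediator_window: tuple[int, int] = (0, 2),
        outcome_window: tuple[int, int] = (0, 3),
        se_method: str = "ml",
        missing: str = "listwise",
        level: float = 0.95,
        n_boot: int = 10_000,
        seed: int = 0,
        stratify_by_arm: bool = False,
    ):
        self.mediators = tuple(mediators)
        self.outcome = outcome
        self.mediator_window = mediator_window
        self.outcome_window = outcome_window
        self.se_method = se_method
        self.missing = missing
        self.level = level
        self.n_boot = n_boot
        self.seed = seed
        self.stratify_by_arm = stratify_by_arm

    def _mediator_list(self) -> list[str]:
        return list(self.mediators)

    def fit(self, X: pd.DataFrame, y=None) -> "MultiMediatorLCS":
        self._fit_system(X)
        return self


def fit_single_mediator(
    table: pd.DataFrame, mediator: str, spec: MediationSpec | None = None, **kwargs
) -> MediationResult:
    """Functional wrapper over :class:`SingleMediatorLCS`."""
    if spec is not None:
        kwargs.setdefault("mediator_window", spec.mediator_window)
        kwargs.setdefault("outcome_window", spec.outcome_window)
        kwargs.setdefault("level", spec.level)
        kwargs.setdefault("n_boot", spec.draws)
        kwargs.setdefault("seed", spec.seed)
    return SingleMediatorLCS(mediator=mediator, **kwargs).fit(table).result_


def fit_multiple_mediator(
    table: pd.DataFrame, spec: MediationSpec | None = None, **kwargs
) -> MediationResult:
    """Functional wrapper over :class:`MultiMediatorLCS`."""
    if spec is not None:
        kwargs.setdefault("mediators", spec.mediators)
        kwargs.setdefault("mediator_window", spec.mediator_window)
        kwargs.setdefault("outcome_window", spec.outcome_window)
        kwargs.setdefault("level", spec.level)
        kwargs.setdefault("n_boot", spec.draws)
        kwargs.setdefault("seed", spec.seed)
    return MultiMediatorLCS(**kwargs).fit(table).result_
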