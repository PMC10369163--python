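"""Latent change score (LCS) regression engine.

An LCS is formed in a structural model by fixing the autoregression
between adjacent waves to 1 and attaching a unit-loading latent factor to
the later wave.  With a single indicator per construct the latent change
is algebraically the observed wave-to-wave difference, so the engine fits
the change-regression system directly by least squares instead of
embedding a general SEM optimizer: the point estimates are identical and
every step is transparent and testable.

Standard errors follow the maximum-likelihood convention by default
(residual variance divided by n, as SEM software reports); an ordinary
least-squares convention (n - p) is available.  z statistics are
estimate / SE with two-sided normal p-values, and Wald confidence
intervals are estimate +/- z_crit * SE.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "LcsError",
    "SingularityError",
    "PathEstimate",
    "EquationFit",
    "ModelFit",
    "ChangeScoreSpec",
    "compute_change_scores",
    "center_predictors",
    "fit_equation",
    "fit_change_model",
    "LatentChangeScoreModel",
]

COND_LIMIT = 1e12  # singularity threshold on the design matrix


class LcsError(ValueError):
    pass


class SingularityError(LcsError):
    pass


@dataclass(frozen=True)
class ChangeScoreSpec:
    """Wave-to-wave change of one variable."""

    variable: str
    from_wave: int
    to_wave: int

    def __post_init__(self) -> None:
        if self.from_wave >= self.to_wave:
            raise LcsError("from_wave must precede to_wave")

    @property
    def name(self) -> str:
        return f"d_{self.variable}_{self.from_wave}{self.to_wave}"


@dataclass(frozen=True)
class PathEstimate:
    """One regression path with its Wald inference."""

    label: str
    estimate: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class EquationFit:
    """One fitted change-regression equation."""

    response: str
    estimates: list[PathEstimate]
    n: int
    policy: str
    se_method: str

    def __getitem__(self, label: str) -> PathEstimate:
        for est in self.estimates:
            if est.label == label:
                return est
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "response": self.response,
                    "term": e.label,
                    "estimate": e.estimate,
                    "se": e.se,
                    "z": e.z,
                    "p": e.p,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n": self.n,
                    "policy": self.policy,
                }
                for e in self.estimates
            ]
        )


@dataclass
class ModelFit:
    """A system of fitted equations (one table-shaped report)."""

    equations: list[EquationFit]
    n_total: int
    policy: str

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([eq.to_frame() for eq in self.equations], ignore_index=True)


def compute_change_scores(
    table: pd.DataFrame, spec: ChangeScoreSpec
) -> pd.Series:
    """Observed difference score ``score(to) - score(from)`` per participant.

    Missing whenever either endpoint is missing.  With unit-fixed loadings
    this equals the latent change.
    """
    lo, hi = f"{spec.variable}_{spec.from_wave}", f"{spec.variable}_{spec.to_wave}"
    for col in (lo, hi):
        if col not in table.columns:
            raise LcsError(f"wave column {col!r} not present in table")
    return (table[hi] - table[lo]).rename(spec.name)


def center_predictors(
    table: pd.DataFrame,
    variables: Sequence[str],
    reference_means: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract each variable's mean (or a supplied reference mean).

    ``reference_means`` lets later-wave depression levels be centered on
    the pretreatment mean rather than their own mean.  Returns a copy of
    the table with the listed columns centered, plus the constants used.
    """
    out = table.copy()
    constants: dict[str, float] = {}
    for var in variables:
        if var not in out.columns:
            raise LcsError(f"variable {var!r} not present in table")
        if reference_means and var in reference_means:
            mean = float(reference_means[var])
        else:
            vals = out[var].dropna()
            if vals.empty:
                raise LcsError(f"variable {var!r} is all-missing; cannot center")
            mean = float(vals.mean())
        out[var] = out[var] - mean
        constants[var] = mean
    return out, constants


# ------------------------------------------------------------ estimation

def _select_rows(
    data: pd.DataFrame, cols: Sequence[str], policy: str
) -> pd.DataFrame:
    if policy == "complete":
        if data[list(cols)].isna().any().any():
            raise LcsError("policy 'complete' requires no missing values in used columns")
        return data
    if policy in {"listwise", "fiml"}:
        return data.dropna(subset=list(cols)) if policy == "listwise" else data
    raise LcsError(f"unknown missing-data policy {policy!r}")


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Predictors involved in (near-)exact linear dependence."""
    flagged = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        coef, res, rank, _ = np.linalg.lstsq(others, xj, rcond=None)
        ssr = float(res[0]) if res.size else float(np.sum((xj - others @ coef) ** 2))
        sst = float(np.sum((xj - xj.mean()) ** 2)) or 1.0
        if ssr / sst < 1e-10:
            flagged.append(names[j])
    return flagged


def _wald(label, est, se, level):
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * stats.norm.sf(abs(z))
    return PathEstimate(label, float(est), float(se), float(z), float(p),
                        float(est - zcrit * se), float(est + zcrit * se), level)


def fit_equation(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    se_method: str = "ml",
    missing: str = "listwise",
    level: float = 0.95,
    labels: dict[str, str] | None = None,
) -> EquationFit:
    """Least-squares fit of one change-regression equation.

    The intercept is always included (labelled ``"intercept"``).  Point
    estimates solve the normal equations via a rank-revealing SVD;
    ``se_method`` chooses the residual-variance denominator (``"ml"``: n,
    ``"ols"``: n - p).  ``missing`` is one of ``"listwise"``,
    ``"complete"`` or ``"fiml"`` (full-information maximum likelihood
    under a multivariate-normal model; see :mod:`lcsmed.fiml`).
    """
    if se_method not in {"ml", "ols"}:
        raise LcsError(f"unknown se_method {se_method!r}")
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        raise LcsError("predictors must be unique")
    cols = [response] + predictors
    for c in cols:
        if c not in data.columns:
            raise LcsError(f"column {c!r} not present in data")
    labels = labels or {}

    if missing == "fiml":
        from .fiml import fiml_regression

        rows = data[cols].dropna(how="all")
        est, se, n_used = fiml_regression(rows[cols].to_numpy(float))
        names = ["intercept"] + predictors
        return EquationFit(
            response=response,
            estimates=[
                _wald(labels.get(nm, nm), est[i], se[i], level)
                for i, nm in enumerate(names)
            ],
            n=n_used,
            policy="fiml",
            se_method="ml",
        )

    rows = _select_rows(data, cols, missing)
    n = len(rows)
    p = len(predictors) + 1
    if n < p + 1:
        raise LcsError(f"{n} usable rows < {p + 1} required for {p} parameters")
    X = np.column_stack([np.ones(n)] + [rows[c].to_numpy(float) for c in predictors])
    y = rows[response].to_numpy(float)
    if np.linalg.cond(X) > COND_LIMIT:
        names = ["intercept"] + predictors
        raise SingularityError(
            "design matrix is numerically singular; collinear terms: "
            + ", ".join(_name_collinear(X, names))
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n if se_method == "ml" else rss / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(cov))
    names = ["intercept"] + predictors
    return EquationFit(
        response=response,
        estimates=[
            _wald(labels.get(nm, nm), beta[i], ses[i], level)
            for i, nm in enumerate(names)
        ],
        n=n,
        policy=missing,
        se_method=se_method,
    )


# ------------------------------------------------------- model estimator

class LatentChangeScoreModel(BaseEstimator):
    """Sequential change-regression system for a four-wave outcome.

    Fits, on a wide trial table with columns ``arm`` and
    ``<outcome>_<wave>`` for waves 0-3:

    1. the (centered) baseline level on centered treatment — a
       randomization balance check;
    2. the 0 -> 1 month change on treatment and baseline level;
    3. the 1 -> 2 month change on treatment, 1-month level and baseline
       level;
    4. the 2 -> 3 month change on treatment, 2-month level and baseline
       level.

    Treatment is mean-centered and all outcome levels are centered on the
    pretreatment mean, so intercepts read as the mean change from the
    previous month for a participant with average pretreatment severity,
    averaged across arms.

    Parameters
    ----------
    outcome : str
        Variable prefix of the outcome columns (default ``"bdi"``).
    se_method : {"ml", "ols"}
        Residual-variance denominator convention.
    missing : {"listwise", "complete", "fiml"}
        Per-equation missing-data policy.
    level : float
        Wald confidence level.

    Attributes
    ----------
    result_ : ModelFit
    equations_ : list of EquationFit
    centering_ : dict mapping centered column -> constant subtracted
    n_ : int, participants in the input table
    """

    def __init__(
        self,
        outcome: str = "bdi",
        se_method: str = "ml",
        missing: str = "listwise",
        level: float = 0.95,
    ):
        self.outcome = outcome
        self.se_method = se_method
        self.missing = missing
        self.level = level

    # -- helpers -------------------------------------------------------
    def _prepare(self, X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
        out = self.outcome
        needed = ["arm"] + [f"{out}_{w}" for w in range(4)]
        for col in needed:
            if col not in X.columns:
                raise LcsError(f"required column {col!r} missing from table")
        if X[f"{out}_0"].isna().any():
            raise LcsError("baseline outcome must be non-missing for every participant")
        if not set(pd.unique(X["arm"].dropna())) <= {0, 1}:
            raise LcsError("arm must be coded 0/1")
        work = X.copy()
        base_mean = float(work[f"{out}_0"].mean())
        work["treatment"] = work["arm"] - work["arm"].mean()
        for w in range(3):
            work[f"level_{w}"] = work[f"{out}_{w}"] - base_mean
        for f, t in ((0, 1), (1, 2), (2, 3)):
            spec = ChangeScoreSpec(out, f, t)
            work[spec.name] = compute_change_scores(work, spec)
        constants = {"treatment": float(X["arm"].mean()), f"{out}_0": base_mean}
        return work, constants

    def fit(self, X: pd.DataFrame, y=None) -> "LatentChangeScoreModel":
        work, constants = self._prepare(X)
        out = self.outcome
        lab = {
            "treatment": "treatment",
            "level_0": "baseline level",
            "level_1": "1-month level",
            "level_2": "2-month level",
        }
        kw = dict(se_method=self.se_method, missing=self.missing, level=self.level, labels=lab)
        equations = [
            fit_equation(work, "level_0", ["treatment"], **kw),
            fit_equation(work, f"d_{out}_01", ["treatment", "level_0"], **kw),
            fit_equation(work, f"d_{out}_12", ["treatment", "level_1", "level_0"], **kw),
            fit_equation(work, f"d_{out}_23", ["treatment", "level_2", "level_0"], **kw),
        ]
        self.equations_ = equations
        self.centering_ = constants
        self.n_ = len(X)
        self.result_ = ModelFit(equations, n_total=len(X), policy=self.missing)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Report shaped like the published efficacy table: one row per
        term with estimate, SE, z, p and the Wald CI."""
        return self.result_.to_frame()


def fit_change_model(
    table: pd.DataFrame, outcome: str = "bdi", **kwargs
) -> ModelFit:
    """Functional wrapper over :class:`LatentChangeScoreModel`."""
    return LatentChangeScoreModel(outcome=outcome, **kwargs).fit(table).result_
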