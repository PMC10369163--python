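"""Clinical-significance metrics: high-end-state functioning, the
Jacobson-Truax reliable change index, Cohen's d and severity tables.

High-end-state functioning means an endpoint depression score inside the
none-to-minimal band (total 0-13): symptoms no longer at a level used to
classify a depressive episode.  The reliable change index (RCI) is
(post - pre) / S_diff with S_diff = sqrt(2 * (sd_pre * sqrt(1 - r))^2);
|RCI| > 1.96 marks change larger than measurement error at 95 %
confidence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import InstrumentSpec, default_registry, severity_distribution

__all__ = [
    "ClinicalError",
    "ClinicalSignificanceSummary",
    "high_end_state_proportion",
    "reliable_change_index",
    "group_rci",
    "cohens_d",
    "clinical_significance",
    "HIGH_END_STATE_MAX",
    "RCI_THRESHOLD",
]

HIGH_END_STATE_MAX = 13
RCI_THRESHOLD = 1.96


class ClinicalError(ValueError):
    pass


def high_end_state_proportion(
    scores: pd.Series, arms: pd.Series | None = None
) -> float | dict:
    """Fraction of non-missing depression scores in the 0-13 band.

    With ``arms`` given, returns a dict per arm; an arm with no
    non-missing scores is reported as ``{"n": 0, "proportion": nan}``
    rather than dividing by zero.
    """
    def _prop(vals: pd.Series):
        vals = vals.dropna()
        if vals.empty:
            return {"n": 0, "proportion": np.nan}
        return {
            "n": int(len(vals)),
            "proportion": float(((vals >= 0) & (vals <= HIGH_END_STATE_MAX)).mean()),
        }

    if arms is None:
        return _prop(scores)["proportion"]
    return {arm: _prop(scores[arms == arm]) for arm in sorted(pd.unique(arms.dropna()))}


def _sdiff(sd_pre: float, reliability: float) -> float:
    if sd_pre <= 0:
        raise ClinicalError("sd_pre must be > 0")
    if not 0 <= reliability < 1:
        raise ClinicalError("reliability must be in [0, 1)")
    return float(np.sqrt(2.0 * (sd_pre * np.sqrt(1.0 - reliability)) ** 2))


def reliable_change_index(pre, post, sd_pre: float, reliability: float):
    """Jacobson-Truax RCI = (post - pre) / S_diff (vectorized)."""
    s_diff = _sdiff(sd_pre, reliability)
    return (np.asarray(post, float) - np.asarray(pre, float)) / s_diff


def group_rci(pre, post, sd_pre: float, reliability: float) -> float:
    """RCI of the group mean change (mean post - mean pre over S_diff)."""
    s_diff = _sdiff(sd_pre, reliability)
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    keep = ~(np.isnan(pre) | np.isnan(post))
    if keep.sum() == 0:
        raise ClinicalError("no complete pre/post pairs")
    return float((post[keep].mean() - pre[keep].mean()) / s_diff)


def cohens_d(changes_treatment, changes_control) -> float:
    """Between-group standardized mean difference of change scores.

    (mean treatment change - mean control change) divided by the pooled
    standard deviation of changes (n - 1 weights).
    """
    t = pd.Series(changes_treatment).dropna().to_numpy(float)
    c = pd.Series(changes_control).dropna().to_numpy(float)
    if len(t) < 2 or len(c) < 2:
        raise ClinicalError("each group needs at least 2 non-missing changes")
    pooled = np.sqrt(
        ((len(t) - 1) * t.var(ddof=1) + (len(c) - 1) * c.var(ddof=1))
        / (len(t) + len(c) - 2)
    )
    if pooled == 0:
        raise ClinicalError("pooled standard deviation of changes is zero")
    return float((t.mean() - c.mean()) / pooled)


@dataclass
class ClinicalSignificanceSummary:
    """Per-arm clinical significance of the baseline -> endpoint contrast."""

    high_end_state: dict
    severity: pd.DataFrame
    cohen_d: float
    group_rci_treatment: float
    rci_individual: pd.DataFrame
    reliability: float
    sd_pre: float
    endpoint_wave: int

    def to_dict(self) -> dict:
        return {
            "high_end_state": {
                str(k): v for k, v in self.high_end_state.items()
            },
            "severity_percent": {
                str(idx): {
                    c: (None if pd.isna(v) else round(float(v), 6))
                    for c, v in row.items()
                }
                for idx, row in self.severity.iterrows()
            },
            "cohen_d": round(self.cohen_d, 6),
            "group_rci_treatment": round(self.group_rci_treatment, 6),
            "reliability": self.reliability,
            "sd_pre": round(self.sd_pre, 6),
            "endpoint_wave": self.endpoint_wave,
            "n_reliable_improvement": int(
                (self.rci_individual["rci"] < -RCI_THRESHOLD).sum()
            ),
            "n_reliable_deterioration": int(
                (self.rci_individual["rci"] > RCI_THRESHOLD).sum()
            ),
        }


def clinical_significance(
    table: pd.DataFrame,
    reliability: float,
    outcome: str = "bdi",
    endpoint_wave: int = 3,
    spec: InstrumentSpec | None = None,
) -> ClinicalSignificanceSummary:
    """Full clinical-significance report for a wide trial table.

    ``reliability`` is the instrument's internal-consistency estimate at
    baseline (supply the item-level Cronbach alpha when item data exist).
    Reports per-arm high-end-state proportions and severity percentages
    at the endpoint wave, individual RCIs, the treatment-group mean-change
    RCI, and Cohen's d on baseline -> endpoint changes.
    """
    spec = spec or default_registry()[outcome]
    pre = table[f"{outcome}_0"]
    post = table[f"{outcome}_{endpoint_wave}"]
    sd_pre = float(pre.std(ddof=1))
    change = post - pre
    arms = table["arm"]

    rci_vals = reliable_change_index(pre, post, sd_pre, reliability)
    rci_frame = pd.DataFrame(
        {"id": table.get("id", pd.RangeIndex(len(table))), "arm": arms, "rci": rci_vals}
    ).dropna(subset=["rci"])

    treat = table[arms == 1]
    sev = severity_distribution(
        pd.DataFrame({"score": post, "arm": arms}), spec, by="arm"
    )
    return ClinicalSignificanceSummary(
        high_end_state=high_end_state_proportion(post, arms),
        severity=sev,
        cohen_d=cohens_d(change[arms == 1], change[arms == 0]),
        group_rci_treatment=group_rci(
            treat[f"{outcome}_0"], treat[f"{outcome}_{endpoint_wave}"], sd_pre, reliability
        ),
        rci_individual=rci_frame,
        reliability=reliability,
        sd_pre=sd_pre,
        endpoint_wave=endpoint_wave,
    )
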