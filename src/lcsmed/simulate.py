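"""Synthetic two-arm trial generator with known ground truth.

Emulates an 8-week text-message CBT trial for young-adult depression:
stratified permuted-block randomization by sex, four assessment waves
(baseline plus 1, 2 and 3 months), a treatment -> mediator-change ->
depression-change structural model over three mediating mechanisms
(behavioral activation ``bads``, cognitive distortions ``cds``,
perseverative thinking ``ptq``), wave-specific attrition, and an
every-other-day message/engagement stream.

The structural model generates total baseline-to-3-month changes

    d_m_i = drift_m_i + a_i * T + eps_i          (per mediator i)
    d_y   = drift_y  + sum_i b_i * d_m_i + c' * T + eps_y

with T the 0/1 arm indicator, and apportions each total change across the
three monthly intervals by fixed wave-profile weights.  Scores are clipped
to instrument bounds and rounded to integers at every wave.  Default
parameters are chosen so that bound truncation is a rare-tail event; see
docs/methods.md.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .instruments import default_registry

__all__ = [
    "ConfigError",
    "StructuralParameters",
    "SimulationConfig",
    "MessageSchedule",
    "stratified_block_randomize",
    "generate_trial",
    "apply_missingness",
    "build_message_schedule",
    "simulate_engagement",
    "MEDIATORS",
    "OUTCOME",
    "WAVES",
    "WEEKLY_TEXT_COUNTS",
]

MEDIATORS = ("bads", "cds", "ptq")
OUTCOME = "bdi"
WAVES = (0, 1, 2, 3)

#: texts per treatment week in the delivered protocol (sums to 474)
WEEKLY_TEXT_COUNTS = (62, 72, 62, 57, 55, 53, 59, 54)
TOTAL_TEXTS = 474
TREATMENT_PERIOD_DAYS = 64
CADENCE_DAYS = 2
TOTAL_PROMPTS = 198
COMPLETION_THRESHOLD = 192


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


def _bounds() -> dict[str, tuple[int, int]]:
    reg = default_registry()
    return {v: (reg[v].score_min, reg[v].score_max) for v in (OUTCOME,) + MEDIATORS}


@dataclass
class StructuralParameters:
    """Ground-truth paths and spreads driving the generator.

    ``a`` maps each mediator to its treatment -> mediator-change path,
    ``b`` to its mediator-change -> depression-change path; ``c_prime`` is
    the direct treatment -> depression-change path.  ``control_drift``
    holds the mean baseline-to-3-month change in the control arm (waitlist
    participants improve somewhat too).  ``wave_weights`` apportions each
    total change across the three monthly intervals and must sum to 1.
    """

    a: dict[str, float] = field(
        default_factory=lambda: {"bads": 7.0, "cds": -14.0, "ptq": -10.0}
    )
    b: dict[str, float] = field(
        default_factory=lambda: {"bads": -0.25, "cds": 0.08, "ptq": 0.22}
    )
    c_prime: float = -3.5
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"bdi": 34.0, "bads": 20.0, "cds": 44.0, "ptq": 42.0}
    )
    baseline_sd: dict[str, float] = field(
        default_factory=lambda: {"bdi": 7.0, "bads": 7.0, "cds": 9.0, "ptq": 8.0}
    )
    control_drift: dict[str, float] = field(
        default_factory=lambda: {"bdi": -4.0, "bads": 1.0, "cds": -3.0, "ptq": -3.0}
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"bdi": 8.0, "bads": 6.0, "cds": 9.0, "ptq": 8.0}
    )
    wave_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            v: (0.55, 0.20, 0.25) for v in ("bdi", "bads", "cds", "ptq")
        }
    )
    #: SD of measurement wobble added at the interior waves (1 and 2)
    #: only, so baseline-to-3-month totals — and hence the mediation
    #: ground truth — are untouched
    interval_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        for v, sd in self.residual_sd.items():
            if sd < 0:
                raise ConfigError(f"residual_sd[{v!r}] must be >= 0")
        if self.interval_noise_sd < 0:
            raise ConfigError("interval_noise_sd must be >= 0")
        for v, w in self.wave_weights.items():
            if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
                raise ConfigError(f"wave_weights[{v!r}] must be 3 weights summing to 1")

    @property
    def indirect(self) -> dict[str, float]:
        """Ground-truth indirect effect per mediator (a_i * b_i)."""
        return {m: self.a[m] * self.b[m] for m in self.a}

    @property
    def total_effect(self) -> float:
        return sum(self.indirect.values()) + self.c_prime


@dataclass
class SimulationConfig:
    """Full configuration of one synthetic trial."""

    n_participants: int = 103
    allocation: tuple[int, int] = (1, 1)
    female_fraction: float = 0.845
    block_size: int = 10
    retention: tuple[float, float, float] = (0.96, 0.96, 0.96)
    structural: StructuralParameters = field(default_factory=StructuralParameters)
    truncation: dict[str, tuple[int, int]] = field(default_factory=_bounds)
    eligibility_min_bdi: int = 20
    monotone_dropout: bool = False
    response_propensity_beta: tuple[float, float] = (1.2, 0.25)
    completion_threshold: int = COMPLETION_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("female_fraction must be in [0, 1]")
        if self.block_size % 2 or self.block_size < 2:
            raise ConfigError("block_size must be a positive even integer")
        if any(not 0 <= r <= 1 for r in self.retention):
            raise ConfigError("retention probabilities must be in [0, 1]")
        st = self.structural
        for v, (lo, hi) in self.truncation.items():
            mu = st.baseline_mean[v]
            if not lo <= mu <= hi:
                raise ConfigError(
                    f"truncation bounds {lo, hi} for {v!r} exclude the baseline mean {mu}"
                )

    # --- round-trippable plain-dict form -------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allocation"] = list(self.allocation)
        d["retention"] = list(self.retention)
        d["truncation"] = {k: list(v) for k, v in self.truncation.items()}
        d["structural"]["wave_weights"] = {
            k: list(v) for k, v in self.structural.wave_weights.items()
        }
        d["response_propensity_beta"] = list(self.response_propensity_beta)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        st = d.pop("structural", {})
        st = dict(st)
        if "wave_weights" in st:
            st["wave_weights"] = {k: tuple(v) for k, v in st["wave_weights"].items()}
        kwargs = {
            "structural": StructuralParameters(**st),
        }
        for key in (
            "n_participants",
            "female_fraction",
            "block_size",
            "eligibility_min_bdi",
            "monotone_dropout",
            "completion_threshold",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "allocation" in d:
            kwargs["allocation"] = tuple(d["allocation"])
        if "retention" in d:
            kwargs["retention"] = tuple(d["retention"])
        if "truncation" in d:
            kwargs["truncation"] = {k: tuple(v) for k, v in d["truncation"].items()}
        if "response_propensity_beta" in d:
            kwargs["response_propensity_beta"] = tuple(d["response_propensity_beta"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _child_seed(seed: int, offset: int) -> int:
    # fixed-offset derivation of operation-level streams from the trial seed
    return (int(seed) * 1_000_003 + offset) % 2**31


def stratified_block_randomize(
    sex_labels: Sequence, block_size: int = 10, seed: int = 0
) -> np.ndarray:
    """Permuted-block 1:1 randomization within strata.

    Every complete consecutive block of ``block_size`` participants inside
    a stratum receives exactly ``block_size / 2`` of each arm; each block
    is an independent uniformly random permutation.  The assignment is a
    deterministic function of (labels, block_size, seed); strata are
    processed in sorted label order.

    Returns the 0/1 arm indicator per participant (1 = treatment).
    """
    if block_size % 2 or block_size < 2:
        raise ConfigError("block_size must be a positive even integer")
    labels = np.asarray(sex_labels)
    arms = np.empty(len(labels), dtype=int)
    rng = np.random.default_rng(seed)
    for stratum in sorted(map(str, set(labels.tolist()))):
        idx = np.flatnonzero(labels.astype(str) == stratum)
        blocks = []
        for _ in range(ceil(len(idx) / block_size)):
            blocks.append(rng.permutation(np.repeat([0, 1], block_size // 2)))
        arms[idx] = np.concatenate(blocks)[: len(idx)]
    return arms


def generate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one complete synthetic trial.

    Returns ``(table, ground_truth)`` where ``table`` is the wide
    per-participant table (columns ``id``, ``arm``, ``sex``, ``phq9_0``
    and ``<scale>_<wave>`` for scales bdi/bads/cds/ptq over waves 0-3)
    and ``ground_truth`` records the exact parameters used.
    """
    st = config.structural
    n = config.n_participants
    rng_sex = np.random.default_rng(_child_seed(config.seed, 0))
    rng_base = np.random.default_rng(_child_seed(config.seed, 2))
    rng_change = np.random.default_rng(_child_seed(config.seed, 3))

    sex = np.where(rng_sex.random(n) < config.female_fraction, "female", "male")
    arm = stratified_block_randomize(sex, config.block_size, _child_seed(config.seed, 1))

    scores: dict[str, list[np.ndarray]] = {}
    for v in (OUTCOME,) + MEDIATORS:
        lo, hi = config.truncation[v]
        if v == OUTCOME:
            lo = max(lo, config.eligibility_min_bdi)  # screened-in sample
        base = np.clip(np.round(rng_base.normal(st.baseline_mean[v], st.baseline_sd[v], n)), lo, hi)
        scores[v] = [base]

    phq9 = np.clip(np.round(rng_base.normal(15.0, 4.0, n)), 10, 27)

    total: dict[str, np.ndarray] = {}
    for m in MEDIATORS:
        total[m] = (
            st.control_drift[m]
            + st.a[m] * arm
            + rng_change.normal(0.0, st.residual_sd[m], n)
        )
    dy = (
        st.control_drift[OUTCOME]
        + st.c_prime * arm
        + rng_change.normal(0.0, st.residual_sd[OUTCOME], n)
    )
    for m in MEDIATORS:
        dy = dy + st.b[m] * total[m]
    total[OUTCOME] = dy

    for v in (OUTCOME,) + MEDIATORS:
        lo, hi = config.truncation[v]
        cum = np.cumsum(st.wave_weights[v])
        for w in range(3):
            wobble = (
                rng_change.normal(0.0, st.interval_noise_sd, n) if w < 2 else 0.0
            )
            scores[v].append(
                np.clip(np.round(scores[v][0] + cum[w] * total[v] + wobble), lo, hi)
            )

    data = {
        "id": [f"P{i + 1:04d}" for i in range(n)],
        "arm": arm,
        "sex": sex,
        "phq9_0": phq9,
    }
    for v in (OUTCOME,) + MEDIATORS:
        for w in WAVES:
            data[f"{v}_{w}"] = scores[v][w]
    table = pd.DataFrame(data)

    ground_truth = {
        "a": dict(st.a),
        "b": dict(st.b),
        "c_prime": st.c_prime,
        "indirect": st.indirect,
        "total_effect": st.total_effect,
        "control_drift": dict(st.control_drift),
        "residual_sd": dict(st.residual_sd),
        "baseline_mean": dict(st.baseline_mean),
        "baseline_sd": dict(st.baseline_sd),
        "wave_weights": {k: list(v) for k, v in st.wave_weights.items()},
        "interval_noise_sd": st.interval_noise_sd,
        "n_treatment": int(arm.sum()),
        "n_control": int(n - arm.sum()),
        "seed": config.seed,
    }
    return table, ground_truth


def apply_missingness(
    table: pd.DataFrame,
    retention: Sequence[float] = (0.96, 0.96, 0.96),
    seed: int = 0,
    monotone: bool = False,
) -> pd.DataFrame:
    """Remove follow-up assessments at random; baseline is never removed.

    Each participant misses follow-up wave ``w`` (1-based) independently
    with probability ``1 - retention[w - 1]``.  In ``monotone`` mode a
    missed wave also removes all later waves (dropout).
    """
    if any(not 0 <= r <= 1 for r in retention):
        raise ConfigError("retention probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    miss = rng.random((n, len(retention))) >= np.asarray(retention)[None, :]
    if monotone:
        miss = np.logical_or.accumulate(miss, axis=1)
    wave_cols = {
        w: [c for c in out.columns if c.endswith(f"_{w}") and not c.startswith("phq9")]
        for w in range(1, len(retention) + 1)
    }
    for w, cols in wave_cols.items():
        rows = miss[:, w - 1]
        out.loc[rows, cols] = np.nan
    return out


@dataclass(frozen=True)
class MessageSchedule:
    """Per-treatment-day message and response-prompt counts."""

    days: tuple[int, ...]  # calendar day numbers, 1-based
    messages: tuple[int, ...]
    prompts: tuple[int, ...]
    period_days: int
    cadence_days: int

    @property
    def n_treatment_days(self) -> int:
        return len(self.days)

    @property
    def total_messages(self) -> int:
        return int(sum(self.messages))

    @property
    def total_prompts(self) -> int:
        return int(sum(self.prompts))

    @property
    def mean_messages_per_day(self) -> float:
        return self.total_messages / self.n_treatment_days


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, float)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def build_message_schedule(
    total_messages: int = TOTAL_TEXTS,
    period_days: int = TREATMENT_PERIOD_DAYS,
    cadence_days: int = CADENCE_DAYS,
    weekly_counts: Sequence[int] = WEEKLY_TEXT_COUNTS,
    total_prompts: int = TOTAL_PROMPTS,
) -> MessageSchedule:
    """Place weekly message totals onto every-other-day treatment days.

    Messaging starts on day 1, so there are ``ceil(period / cadence)``
    treatment days.  Each week's count is split as evenly as possible
    (largest remainder) across that week's treatment days; response
    prompts are apportioned proportionally to daily message counts.
    """
    if sum(weekly_counts) != total_messages:
        raise ConfigError(
            f"weekly counts sum to {sum(weekly_counts)}, expected {total_messages}"
        )
    days = tuple(range(1, period_days + 1, cadence_days))
    week_len = period_days / len(weekly_counts)
    per_week: dict[int, list[int]] = {w: [] for w in range(len(weekly_counts))}
    for d in days:
        per_week[min(int((d - 1) // week_len), len(weekly_counts) - 1)].append(d)
    messages = np.zeros(len(days), int)
    day_pos = {d: i for i, d in enumerate(days)}
    for w, count in enumerate(weekly_counts):
        wdays = per_week[w]
        if count and not wdays:
            raise ConfigError(f"week {w + 1} has messages but no treatment days")
        alloc = _largest_remainder(count, np.ones(len(wdays)))
        for d, m in zip(wdays, alloc):
            messages[day_pos[d]] = m
    prompts = _largest_remainder(total_prompts, messages.astype(float))
    return MessageSchedule(
        days=days,
        messages=tuple(int(m) for m in messages),
        prompts=tuple(int(p) for p in prompts),
        period_days=period_days,
        cadence_days=cadence_days,
    )


def simulate_engagement(
    schedule: MessageSchedule,
    response_propensity: Sequence[float],
    completion_threshold: int = COMPLETION_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial per-day response counts and the completer flag.

    Each participant responds to each day's prompts independently with
    their own propensity; a completer reaches ``completion_threshold``
    total responses (the protocol's >= 95 % rule as printed).

    Returns one row per participant with ``responses_day_<d>`` columns,
    ``total_responses`` and ``completer``.
    """
    p = np.asarray(response_propensity, float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("response propensities must be in [0, 1]")
    if completion_threshold > schedule.total_prompts:
        raise ConfigError(
            f"completion threshold {completion_threshold} exceeds total prompts "
            f"{schedule.total_prompts}"
        )
    rng = np.random.default_rng(seed)
    prompts = np.asarray(schedule.prompts)
    responses = rng.binomial(prompts[None, :], p[:, None])
    out = pd.DataFrame(
        responses, columns=[f"responses_day_{d}" for d in schedule.days]
    )
    out.insert(0, "participant", np.arange(len(p)))
    out["total_responses"] = responses.sum(axis=1)
    out["completer"] = out["total_responses"] >= completion_threshold
    return out
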