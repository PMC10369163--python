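"""Published summary statistics of the 8-week text-message CBT trial for
young-adult depression that this package's pipeline models.

These constants are *inputs* for reproduction runs (``lcsmed
reproduce-tables``): feeding the trial's reported path estimates through
:func:`lcsmed.mediation.indirect_summary` recovers its reported indirect,
total and percent-mediated values, and the message-protocol constants
drive :func:`lcsmed.simulate.build_message_schedule`.

Where a reported indirect effect differs in the last digit from the
product of the (rounded) printed paths, the reported indirect carries
more precision and is used as-is for total/percent arithmetic.
"""
from __future__ import annotations

import pandas as pd

from .mediation import indirect_summary
from .simulate import (
    CADENCE_DAYS,
    TOTAL_PROMPTS,
    TOTAL_TEXTS,
    TREATMENT_PERIOD_DAYS,
    WEEKLY_TEXT_COUNTS,
    build_message_schedule,
)

__all__ = [
    "SINGLE_MEDIATOR_PATHS",
    "MULTI_MEDIATOR_PATHS",
    "ARM_SIZES",
    "reproduce_mediation_summaries",
    "reproduce_schedule_summary",
    "reproduce_centering",
]

#: reported single-mediator models: a, b, c' paths and the reported
#: indirect effect (behavioral activation, cognitive distortions,
#: perseverative thinking)
SINGLE_MEDIATOR_PATHS = {
    "bads": {"a": 7.03, "b": -0.75, "c_prime": -4.01, "indirect": -5.27},
    "cds": {"a": -15.98, "b": 0.25, "c_prime": -5.67, "indirect": -4.01},
    "ptq": {"a": -10.33, "b": 0.50, "c_prime": -5.18, "indirect": -5.12},
}

#: reported simultaneous (multi-mediator) model
MULTI_MEDIATOR_PATHS = {
    "a": {"bads": 7.29, "cds": -18.72, "ptq": -11.28},
    "b": {"bads": -0.29, "cds": 0.06, "ptq": 0.25},
    "c_prime": -3.52,
    "indirect": {"bads": -2.09, "cds": -1.14, "ptq": -2.83},
    "combined_indirect": -6.07,
}

#: randomized arm sizes (treatment, control)
ARM_SIZES = (50, 53)


def reproduce_mediation_summaries() -> pd.DataFrame:
    """Indirect / total / percent-mediated arithmetic from the reported
    path estimates, one row per (model, mediator) plus the combined row."""
    rows = []
    for med, paths in SINGLE_MEDIATOR_PATHS.items():
        ab, _, _ = indirect_summary(paths["a"], paths["b"], paths["c_prime"])
        indirect = paths["indirect"]
        total = indirect + paths["c_prime"]
        percent = 100.0 * indirect / total
        rows.append(
            {
                "model": "single",
                "mediator": med,
                "a": paths["a"],
                "b": paths["b"],
                "c_prime": paths["c_prime"],
                "a_times_b": round(ab, 4),
                "indirect": indirect,
                "total": round(total, 2),
                "percent_mediated": round(percent, 1),
            }
        )
    mm = MULTI_MEDIATOR_PATHS
    total = mm["combined_indirect"] + mm["c_prime"]
    for med in mm["a"]:
        rows.append(
            {
                "model": "multi",
                "mediator": med,
                "a": mm["a"][med],
                "b": mm["b"][med],
                "c_prime": mm["c_prime"],
                "a_times_b": round(mm["a"][med] * mm["b"][med], 4),
                "indirect": mm["indirect"][med],
                "total": round(total, 2),
                "percent_mediated": round(100.0 * mm["indirect"][med] / total, 1),
            }
        )
    rows.append(
        {
            "model": "multi",
            "mediator": "combined",
            "c_prime": mm["c_prime"],
            "indirect": mm["combined_indirect"],
            "total": round(total, 2),
            "percent_mediated": round(100.0 * mm["combined_indirect"] / total, 1),
        }
    )
    return pd.DataFrame(rows)


def reproduce_schedule_summary() -> dict:
    """Dose arithmetic of the delivered message protocol."""
    schedule = build_message_schedule(
        TOTAL_TEXTS, TREATMENT_PERIOD_DAYS, CADENCE_DAYS, WEEKLY_TEXT_COUNTS, TOTAL_PROMPTS
    )
    return {
        "treatment_days": schedule.n_treatment_days,
        "total_messages": schedule.total_messages,
        "mean_messages_per_treatment_day": round(schedule.mean_messages_per_day, 4),
        "total_prompts": schedule.total_prompts,
        "weekly_counts_sum": int(sum(WEEKLY_TEXT_COUNTS)),
    }


def reproduce_centering() -> dict:
    """Centered treatment coding for the trial's arm sizes."""
    n_t, n_c = ARM_SIZES
    mean = n_t / (n_t + n_c)
    return {
        "treatment_centered": round(1.0 - mean, 2),
        "control_centered": round(0.0 - mean, 2),
    }
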