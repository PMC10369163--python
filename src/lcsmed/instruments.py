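"""Questionnaire scoring, severity banding, eligibility and reliability.

Five sum-score instruments are built in: the 21-item depression severity
inventory (``bdi``, items 0-3, total 0-63, four severity bands), the 9-item
depression screen (``phq9``, items 0-3, total 0-27, eligibility cut at 10),
the 9-item behavioral-activation short form (``bads``, items 0-6), the
15-item perseverative-thinking questionnaire (``ptq``, items 0-4) and the
10-item cognitive-distortions scale (``cds``, items 0-7).  All scales are
scored by summing item responses; severity bands are closed integer
intervals that partition the total-score range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentSpec",
    "ItemResponseTable",
    "InstrumentError",
    "default_registry",
    "load_registry",
    "save_registry",
    "score_scale",
    "classify_severity",
    "classify_bdi_severity",
    "phq9_eligible",
    "cronbach_alpha",
    "severity_distribution",
    "read_item_table",
    "write_item_table",
    "read_wide_scores",
    "write_wide_scores",
]


class InstrumentError(ValueError):
    """Raised for invalid instrument metadata or out-of-range responses."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Metadata for a sum-score questionnaire.

    Parameters
    ----------
    name : str
        Short identifier (used as the column prefix in wide tables).
    n_items : int
        Number of items, at least 1.
    item_min, item_max : int
        Inclusive response range for every item.
    bands : tuple of (label, low, high)
        Ordered, non-overlapping closed integer intervals that exactly
        cover ``[n_items * item_min, n_items * item_max]``.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise InstrumentError(f"{self.name}: n_items must be >= 1")
        if self.item_min >= self.item_max:
            raise InstrumentError(f"{self.name}: item_min must be < item_max")
        lo, hi = self.score_min, self.score_max
        expected = lo
        for label, blo, bhi in self.bands:
            if blo != expected or bhi < blo:
                raise InstrumentError(
                    f"{self.name}: bands must be ordered, non-overlapping and "
                    f"exhaustive over [{lo}, {hi}] (problem at {label!r})"
                )
            expected = bhi + 1
        if expected != hi + 1:
            raise InstrumentError(f"{self.name}: bands do not cover the range up to {hi}")

    @property
    def score_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.item_max

    def band_of(self, score: int) -> str:
        """Severity-band label containing ``score``."""
        if not (self.score_min <= score <= self.score_max):
            raise InstrumentError(
                f"{self.name}: score {score} outside [{self.score_min}, {self.score_max}]"
            )
        for label, lo, hi in self.bands:
            if lo <= score <= hi:
                return label
        raise AssertionError("bands are exhaustive by construction")

    @property
    def band_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bands)


def _full_range_band(n_items: int, item_min: int, item_max: int):
    return (("full-range", n_items * item_min, n_items * item_max),)


BDI_BANDS = (
    ("none-to-minimal", 0, 13),
    ("mild", 14, 19),
    ("moderate", 20, 28),
    ("severe", 29, 63),
)

PHQ9_BANDS = (
    ("none-to-minimal", 0, 4),
    ("mild", 5, 9),
    ("moderate", 10, 14),
    ("moderately-severe", 15, 19),
    ("severe", 20, 27),
)

PHQ9_ELIGIBILITY_CUTOFF = 10


def default_registry() -> dict[str, InstrumentSpec]:
    """The five built-in instruments keyed by name."""
    return {
        "bdi": InstrumentSpec("bdi", 21, 0, 3, BDI_BANDS),
        "phq9": InstrumentSpec("phq9", 9, 0, 3, PHQ9_BANDS),
        "bads": InstrumentSpec("bads", 9, 0, 6, _full_range_band(9, 0, 6)),
        "ptq": InstrumentSpec("ptq", 15, 0, 4, _full_range_band(15, 0, 4)),
        # printed as "0=never to 7=all the time"; range configurable here
        "cds": InstrumentSpec("cds", 10, 0, 7, _full_range_band(10, 0, 7)),
    }


def load_registry(path: str | Path) -> dict[str, InstrumentSpec]:
    """Load an instrument registry from a YAML file.

    Expected layout per instrument::

        bdi:
          n_items: 21
          item_min: 0
          item_max: 3
          bands: [[none-to-minimal, 0, 13], [mild, 14, 19], ...]
    """
    raw = yaml.safe_load(Path(path).read_text())
    registry = {}
    for name, cfg in raw.items():
        bands = tuple((str(b[0]), int(b[1]), int(b[2])) for b in cfg["bands"])
        registry[name] = InstrumentSpec(
            name, int(cfg["n_items"]), int(cfg["item_min"]), int(cfg["item_max"]), bands
        )
    return registry


def save_registry(registry: Mapping[str, InstrumentSpec], path: str | Path) -> None:
    out = {
        name: {
            "n_items": spec.n_items,
            "item_min": spec.item_min,
            "item_max": spec.item_max,
            "bands": [[label, lo, hi] for label, lo, hi in spec.bands],
        }
        for name, spec in registry.items()
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


@dataclass
class ItemResponseTable:
    """Item-level responses for one instrument at one wave.

    ``data`` is participants x items; the index holds participant ids.
    Missing responses are NaN.  Validation happens on construction.
    """

    instrument: InstrumentSpec
    wave: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.instrument.n_items:
            raise InstrumentError(
                f"{self.instrument.name}: expected {self.instrument.n_items} item "
                f"columns, got {self.data.shape[1]}"
            )
        values = self.data.to_numpy(float)
        bad = np.where(
            ~np.isnan(values)
            & ((values < self.instrument.item_min) | (values > self.instrument.item_max))
        )
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise InstrumentError(
                f"{self.instrument.name}: response {values[i, j]:g} out of range "
                f"[{self.instrument.item_min}, {self.instrument.item_max}] for "
                f"participant {self.data.index[i]!r}, item {self.data.columns[j]!r}"
            )

    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index


def score_scale(items: ItemResponseTable, missing: str = "strict") -> pd.DataFrame:
    """Sum item responses into one severity score per participant.

    Parameters
    ----------
    items : ItemResponseTable
    missing : {"strict", "mean_impute"}
        ``"strict"`` (default): any missing item makes the scale score
        missing.  ``"mean_impute"``: missing items are replaced by the
        participant's mean over observed items, and the sum is rounded to
        the nearest integer.

    Returns
    -------
    DataFrame with columns ``participant_id``, ``wave``, ``instrument``,
    ``score`` (float, NaN when missing) and ``band`` (None when missing).
    """
    if missing not in {"strict", "mean_impute"}:
        raise ValueError(f"unknown missing policy {missing!r}")
    spec = items.instrument
    values = items.data.to_numpy(float)
    n_missing = np.isnan(values).sum(axis=1)
    if missing == "strict":
        scores = np.where(n_missing == 0, np.nansum(values, axis=1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            row_mean = np.nanmean(values, axis=1)
        filled = np.where(np.isnan(values), row_mean[:, None], values)
        scores = np.round(filled.sum(axis=1))
        scores[n_missing == spec.n_items] = np.nan
    bands = [None if np.isnan(s) else spec.band_of(int(s)) for s in scores]
    return pd.DataFrame(
        {
            "participant_id": items.participant_ids,
            "wave": items.wave,
            "instrument": spec.name,
            "score": scores,
            "band": bands,
        }
    ).reset_index(drop=True)


def classify_severity(spec: InstrumentSpec, score: int) -> str:
    """Severity-band label for a total score (closed-interval cut-offs)."""
    return spec.band_of(score)


def classify_bdi_severity(score: int) -> str:
    """Depression severity band: 0-13 none-to-minimal, 14-19 mild,
    20-28 moderate, 29-63 severe."""
    return default_registry()["bdi"].band_of(score)


def phq9_eligible(score: int) -> bool:
    """True when the 9-item depression screen total meets the trial's
    eligibility bar (score >= 10, i.e. at least moderate symptoms)."""
    spec = default_registry()["phq9"]
    if not (spec.score_min <= score <= spec.score_max):
        raise InstrumentError(f"phq9 score {score} outside [0, {spec.score_max}]")
    return score >= PHQ9_ELIGIBILITY_CUTOFF


def cronbach_alpha(items: ItemResponseTable) -> float:
    """Internal-consistency reliability of a sum score.

    alpha = k/(k-1) * (1 - sum of item variances / total-score variance),
    computed on complete-case rows with ``ddof=1`` variances.
    """
    data = items.data.dropna()
    k = items.instrument.n_items
    if k < 2:
        raise InstrumentError("cronbach_alpha requires at least 2 items")
    if len(data) < 2:
        raise InstrumentError("cronbach_alpha requires at least 2 complete rows")
    values = data.to_numpy(float)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InstrumentError("total-score variance is zero; alpha undefined")
    item_var = values.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)


def severity_distribution(
    scores: pd.DataFrame, spec: InstrumentSpec, by: str = "arm"
) -> pd.DataFrame:
    """Per-group percentage of participants in each severity band.

    ``scores`` needs a ``score`` column and the grouping column ``by``.
    Percentages use non-missing scores as the denominator and sum to 100
    per group (up to floating point).  Empty groups are reported with
    ``n = 0`` and NaN percentages rather than raising.
    """
    rows = []
    for group, sub in scores.groupby(by, sort=True):
        vals = sub["score"].dropna()
        row = {by: group, "n": int(len(vals))}
        for label, lo, hi in spec.bands:
            if len(vals):
                row[label] = 100.0 * ((vals >= lo) & (vals <= hi)).sum() / len(vals)
            else:
                row[label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(by)


# ----------------------------------------------------------------- CSV IO

def read_item_table(
    path: str | Path, spec: InstrumentSpec, wave: int, id_column: str = "participant_id"
) -> ItemResponseTable:
    """Read an item-level CSV (one file per instrument per wave).

    The header holds item identifiers; empty cells are missing.
    """
    frame = pd.read_csv(path).set_index(id_column)
    return ItemResponseTable(spec, wave, frame)


def write_item_table(items: ItemResponseTable, path: str | Path) -> None:
    items.data.to_csv(path, index_label="participant_id")


def read_wide_scores(path: str | Path) -> pd.DataFrame:
    """Read a wide score-level table: one row per participant, columns
    ``id``, ``arm``, ``sex`` and ``<instrument>_<wave>``."""
    return pd.read_csv(path)


def write_wide_scores(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
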