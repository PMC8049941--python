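"""Cognitive-model predictor variables for PIAT items.

Each item is described by the features the explanatory difficulty model uses:

* ``level`` — number of imagined (silent) arrows;
* ``heard_range`` — number of unique tones sounded during set-up, start note
  included;
* ``probability_probe_last_heard`` — empirical probability of the signed
  distance between the last heard note and the probe, taken over a reference
  bank;
* ``probe_trueim_absdiff`` — absolute distance between the probe and the true
  imagined final note (0 on correct-probe trials, 1 or 2 on incorrect ones);
* ``probability_probe`` — empirical probability of the probe offset among
  bank items with the same total arrow count;
* ``probe_is_startnote`` — whether the probe equals the start note (never
  true for generated banks);
* ``probe_accuracy`` — the correct/incorrect switch the joint model
  interacts every predictor with.

The two probability features are relative frequencies over a bank — no
smoothing; a value unseen in the reference bank has probability 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .itemgen import ItemBank, PIATItem

__all__ = [
    "FeatureVector",
    "BankTables",
    "heard_range",
    "distance_table",
    "probability_probe_last_heard",
    "probe_trueim_absdiff",
    "probability_probe",
    "bank_tables",
    "featurize",
    "features_frame",
    "TABLE_COLUMNS",
]

#: Canonical column names for tabular export, matching the difficulty model's
#: predictor naming.
TABLE_COLUMNS = [
    "item_id",
    "Level",
    "Heard_Range",
    "ProbabilityProbe_LastHeard",
    "ProbeTrueIm_AbsDiff",
    "ProbeNote_is_StartNote",
    "Probability_Probe",
    "Probe_Accuracy",
]


@dataclass(frozen=True)
class FeatureVector:
    level: int
    heard_range: int
    probability_probe_last_heard: float
    probe_trueim_absdiff: int
    probe_is_startnote: bool
    probability_probe: float
    probe_accuracy: bool


def heard_range(item: PIATItem) -> int:
    """Number of unique tones sounded during set-up, including the start note."""
    return len({0, *item.walk.heard_positions})


def signed_probe_distance(item: PIATItem) -> int:
    """Signed scale-step distance from the last heard note to the probe."""
    return item.probe_offset - item.walk.last_heard_offset


def distance_table(
    items: Iterable[PIATItem] | ItemBank, absolute: bool = False
) -> dict[int, float]:
    """Empirical distribution of the probe vs last-heard-note distance.

    Signed by default; ``absolute=True`` folds the sign.  Frequencies sum
    to 1 over the bank.
    """
    counts: dict[int, int] = {}
    n = 0
    for item in items:
        d = signed_probe_distance(item)
        if absolute:
            d = abs(d)
        counts[d] = counts.get(d, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("distance_table requires a nonempty bank")
    return {d: c / n for d, c in sorted(counts.items())}


def probability_probe_last_heard(
    item: PIATItem, table: Mapping[int, float], absolute: bool = False
) -> float:
    d = signed_probe_distance(item)
    if absolute:
        d = abs(d)
    return table.get(d, 0.0)


def probe_trueim_absdiff(item: PIATItem) -> int:
    return abs(item.probe_offset - item.true_final_offset)


def _arrow_count(item: PIATItem) -> int:
    return item.walk.n_heard + item.level


def probe_offset_tables(
    items: Iterable[PIATItem] | ItemBank,
) -> dict[int, dict[int, float]]:
    """Per-arrow-count empirical distributions of the probe offset."""
    counts: dict[int, dict[int, int]] = {}
    for item in items:
        sub = counts.setdefault(_arrow_count(item), {})
        sub[item.probe_offset] = sub.get(item.probe_offset, 0) + 1
    out: dict[int, dict[int, float]] = {}
    for k, sub in counts.items():
        n = sum(sub.values())
        out[k] = {o: c / n for o, c in sorted(sub.items())}
    return out


def probability_probe(
    item: PIATItem, tables: Mapping[int, Mapping[int, float]]
) -> float:
    """Probability of the item's probe offset among bank items with the same
    total arrow count."""
    return tables.get(_arrow_count(item), {}).get(item.probe_offset, 0.0)


@dataclass(frozen=True)
class BankTables:
    """Bank-level empirical tables the probability features are read from."""

    distance: Mapping[int, float]
    probe_by_arrow_count: Mapping[int, Mapping[int, float]]
    absolute_distance: bool = False


def bank_tables(
    items: Iterable[PIATItem] | ItemBank, absolute_distance: bool = False
) -> BankTables:
    items = list(items)
    return BankTables(
        distance=distance_table(items, absolute=absolute_distance),
        probe_by_arrow_count=probe_offset_tables(items),
        absolute_distance=absolute_distance,
    )


def featurize(item: PIATItem, tables: BankTables) -> FeatureVector:
    """Assemble the full predictor vector of one item (pure; idempotent)."""
    if tables is None:
        raise ValueError("bank tables are required to featurize an item")
    return FeatureVector(
        level=item.level,
        heard_range=heard_range(item),
        probability_probe_last_heard=probability_probe_last_heard(
            item, tables.distance, absolute=tables.absolute_distance
        ),
        probe_trueim_absdiff=probe_trueim_absdiff(item),
        probe_is_startnote=item.probe_offset == 0,
        probability_probe=probability_probe(item, tables.probe_by_arrow_count),
        probe_accuracy=item.probe_correct,
    )


def features_frame(
    bank: ItemBank | Iterable[PIATItem], tables: BankTables | None = None
) -> pd.DataFrame:
    """One row per item with the canonical predictor column names."""
    items = list(bank)
    if tables is None:
        tables = bank_tables(items)
    rows = []
    for item in items:
        f = featurize(item, tables)
        rows.append(
            {
                "item_id": item.item_id,
                "Level": f.level,
                "Heard_Range": f.heard_range,
                "ProbabilityProbe_LastHeard": f.probability_probe_last_heard,
                "ProbeTrueIm_AbsDiff": f.probe_trueim_absdiff,
                "ProbeNote_is_StartNote": f.probe_is_startnote,
                "Probability_Probe": f.probability_probe,
                "Probe_Accuracy": f.probe_accuracy,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
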