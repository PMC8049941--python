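"""Serialization of item banks, calibrated banks, and response tables.

Structured artifacts are JSON (UTF-8, LF), tabular data is CSV with fixed
column order.  Every bank file embeds the generation seed and a digest of the
generating config, and carries a schema version that readers check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .features import FeatureVector
from .irt import CalibratedItem, ModelParams
from .itemgen import (
    KEY_SIGNATURES,
    ArrowWalk,
    GenerationConfig,
    ItemBank,
    PIATItem,
)

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_bank",
    "read_bank",
    "write_calibrated_bank",
    "read_calibrated_bank",
    "write_responses",
    "read_responses",
    "write_model_params",
    "read_model_params",
    "config_digest",
]

SCHEMA_VERSION = 1

RESPONSE_COLUMNS = ["participant_id", "item_id", "correct"]


class SchemaError(ValueError):
    """Unknown or incompatible artifact schema version."""


def config_digest(config: GenerationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _item_to_dict(item: PIATItem) -> dict:
    return {
        "id": item.item_id,
        "key": item.key.name,
        "start_degree": item.walk.start_degree,
        "heard_steps": list(item.walk.heard_steps),
        "silent_steps": list(item.walk.silent_steps),
        "probe_offset": item.probe_offset,
        "probe_correct": item.probe_correct,
    }


def _item_from_dict(d: dict) -> PIATItem:
    walk = ArrowWalk(
        d["start_degree"], tuple(d["heard_steps"]), tuple(d["silent_steps"])
    )
    return PIATItem(
        d["id"], KEY_SIGNATURES[d["key"]], walk, d["probe_offset"], d["probe_correct"]
    )


def write_bank(bank: ItemBank, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": bank.config.seed,
        "config": dataclasses.asdict(bank.config),
        "config_digest": config_digest(bank.config),
        "items": [_item_to_dict(it) for it in bank.items],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def _load_json(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: parse error at byte offset {e.pos}") from e
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    return doc


def read_bank(path: str | Path) -> ItemBank:
    doc = _load_json(path)
    cfg = doc["config"]
    for key in ("levels", "heard_counts", "start_degrees", "accuracies", "keys"):
        cfg[key] = tuple(cfg[key])
    config = GenerationConfig(**cfg)
    return ItemBank([_item_from_dict(d) for d in doc["items"]], config)


def write_calibrated_bank(
    calibrated: list[CalibratedItem],
    params: ModelParams,
    path: str | Path,
    bank: ItemBank | None = None,
) -> None:
    """Bank JSON augmented with features, easiness, and difficulty."""
    by_id = {it.item_id: it for it in bank.items} if bank is not None else {}
    items = []
    for cal in calibrated:
        d = _item_to_dict(by_id[cal.item_id]) if cal.item_id in by_id else {
            "id": cal.item_id
        }
        d["features"] = dataclasses.asdict(cal.features)
        d["easiness"] = cal.easiness
        d["difficulty"] = cal.difficulty
        items.append(d)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model_params": _params_to_dict(params),
        "items": items,
    }
    if bank is not None:
        doc["seed"] = bank.config.seed
        doc["config_digest"] = config_digest(bank.config)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_calibrated_bank(
    path: str | Path,
) -> tuple[list[CalibratedItem], ModelParams]:
    doc = _load_json(path)
    params = _params_from_dict(doc["model_params"])
    out = []
    for d in doc["items"]:
        out.append(
            CalibratedItem(
                d["id"], FeatureVector(**d["features"]), d["easiness"], d["difficulty"]
            )
        )
    return out, params


def _params_to_dict(params: ModelParams) -> dict:
    return {
        "coefficients": dict(params.coefficients),
        "guessing": params.guessing,
        "inattention": params.inattention,
        "discrimination": params.discrimination,
        "scale": params.scale,
    }


def _params_from_dict(d: dict) -> ModelParams:
    return ModelParams(
        coefficients=d["coefficients"],
        guessing=d["guessing"],
        inattention=d["inattention"],
        discrimination=d["discrimination"],
        scale=d["scale"],
    )


def write_model_params(params: ModelParams, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **_params_to_dict(params)}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_model_params(path: str | Path) -> ModelParams:
    return _params_from_dict(_load_json(path))


def write_responses(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, RESPONSE_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a long-format response CSV, validating the binary response column.

    A non-binary ``correct`` value raises a ValueError naming the 1-based
    data row.  An empty table (header only) is valid.
    """
    table = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~table["correct"].isin([0, 1])
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(
            f"{path}: non-binary 'correct' value "
            f"{table.loc[row - 1, 'correct']!r} at data row {row}"
        )
    table["correct"] = table["correct"].astype(int)
    return table[RESPONSE_COLUMNS]
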