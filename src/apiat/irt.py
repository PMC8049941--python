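"""Explanatory 4PL item-response model with constant discrimination.

Response probability for a respondent with ability ``theta`` on an item of
difficulty ``b``:

    P(correct) = c + (d - c) * logistic(a * (theta - b))

with guessing floor ``c``, inattention ceiling ``d`` and constant
discrimination ``a`` (the logistic is in the natural metric, no 1.7 factor).
Item difficulty is not freely estimated per item; it comes from a linear
"easiness" predictor over the item's cognitive features, with separate
coefficients for correct-probe and incorrect-probe trials:

    eta = intercept + sum_j beta[branch:feature_j] * x_j,   b = -eta / s

where ``s`` rescales difficulty so one unit corresponds to one standard
deviation of respondent ability in a calibration sample.

The default coefficients are the fitted joint calibration model; the default
asymptotes are c = 0.3, d = 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .features import FeatureVector, bank_tables, featurize
from .itemgen import ItemBank

__all__ = [
    "COEFFICIENT_NAMES",
    "DEFAULT_COEFFICIENTS",
    "ModelParams",
    "CalibratedItem",
    "easiness",
    "response_probability",
    "log_likelihood",
    "item_information",
    "calibrate_bank",
]

#: The eight named coefficients of the joint explanatory model.  Branch
#: prefixes select which coefficient applies: "correct:" terms are active on
#: correct-probe items, "incorrect:" terms on incorrect-probe items; the
#: intercept is shared.
COEFFICIENT_NAMES = (
    "intercept",
    "correct:probability_probe_last_heard",
    "incorrect:probability_probe_last_heard",
    "correct:level",
    "incorrect:level",
    "incorrect:probe_trueim_absdiff",
    "correct:heard_range",
    "incorrect:heard_range",
)

#: Fitted joint-model coefficients from the calibration study.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.918,
    "correct:probability_probe_last_heard": 2.778,
    "incorrect:probability_probe_last_heard": 0.228,
    "correct:level": -0.176,
    "incorrect:level": -0.157,
    "incorrect:probe_trueim_absdiff": 1.151,
    "correct:heard_range": 0.157,
    "incorrect:heard_range": -0.553,
}


@dataclass(frozen=True)
class ModelParams:
    """Coefficients plus the four constant response-curve parameters."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    guessing: float = 0.3       # lower asymptote c
    inattention: float = 0.95   # upper asymptote d
    discrimination: float = 1.0  # constant a
    scale: float = 1.0           # ability-SD scale s

    def __post_init__(self) -> None:
        if not 0.0 <= self.guessing < 1.0:
            raise ValueError("guessing must be in [0, 1)")
        if not self.guessing < self.inattention <= 1.0:
            raise ValueError("inattention must satisfy c < d <= 1")
        if self.discrimination <= 0 or self.scale <= 0:
            raise ValueError("discrimination and scale must be positive")
        missing = [n for n in COEFFICIENT_NAMES if n not in self.coefficients]
        if missing:
            raise ValueError(f"missing coefficients: {missing}")


def _branch_terms(features: FeatureVector) -> dict[str, float]:
    """Active (coefficient-name, feature-value) terms for one item."""
    if features.probe_accuracy:
        return {
            "correct:probability_probe_last_heard":
                features.probability_probe_last_heard,
            "correct:level": features.level,
            "correct:heard_range": features.heard_range,
        }
    return {
        "incorrect:probability_probe_last_heard":
            features.probability_probe_last_heard,
        "incorrect:level": features.level,
        "incorrect:probe_trueim_absdiff": features.probe_trueim_absdiff,
        "incorrect:heard_range": features.heard_range,
    }


def easiness(features: FeatureVector, params: ModelParams) -> float:
    """Linear predictor eta of one item (larger = easier at ability 0)."""
    coef = params.coefficients
    eta = coef["intercept"]
    for name, value in _branch_terms(features).items():
        if name not in coef:
            raise ValueError(f"missing coefficient: {name}")
        eta += coef[name] * value
    return float(eta)


def response_probability(theta, b, params: ModelParams):
    """4PL probability of a correct response; vectorizes over theta and b."""
    c, d, a = params.guessing, params.inattention, params.discrimination
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    p = c + (d - c) * expit(a * (theta - b))
    return float(p) if p.ndim == 0 else p


def _as_response_arrays(
    responses: Sequence[tuple[float, int]] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if (
        isinstance(responses, tuple)
        and len(responses) == 2
        and np.ndim(responses[0]) == 1
    ):
        b, x = responses
    else:
        arr = np.asarray(list(responses), dtype=float)
        if arr.size == 0:
            return np.empty(0), np.empty(0)
        b, x = arr[:, 0], arr[:, 1]
    return np.asarray(b, dtype=float), np.asarray(x, dtype=float)


def log_likelihood(theta, responses, params: ModelParams) -> float:
    """Binomial log-likelihood of a response set at ability ``theta``.

    ``responses`` is a sequence of (difficulty, correct) pairs or an
    ``(b_array, x_array)`` tuple.  Finite for any bounded theta since the
    asymptotes keep P away from 0 and 1 whenever 0 < c and d < 1.
    """
    b, x = _as_response_arrays(responses)
    if b.size == 0:
        raise ValueError("log_likelihood requires at least one response")
    p = response_probability(theta, b, params)
    return float(np.sum(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def item_information(theta, b, params: ModelParams):
    """Fisher information of a single 4PL item: (P')^2 / (P (1-P))."""
    c, d, a = params.guessing, params.inattention, params.discrimination
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    s = expit(a * (theta - b))
    p = c + (d - c) * s
    dp = (d - c) * a * s * (1.0 - s)
    info = dp * dp / (p * (1.0 - p))
    return float(info) if info.ndim == 0 else info


@dataclass(frozen=True)
class CalibratedItem:
    """An item with its model-implied easiness and difficulty."""

    item_id: str
    features: FeatureVector
    easiness: float
    difficulty: float


def calibrate_bank(
    bank: ItemBank | Iterable,
    params: ModelParams | None = None,
    tables=None,
) -> list[CalibratedItem]:
    """Attach easiness eta and difficulty b = -eta / s to every bank item.

    Empirical probability tables default to the bank itself, so the combined
    calibration + extension bank is calibrated against its own distributions.
    """
    params = params or ModelParams()
    items = list(bank)
    if tables is None:
        tables = bank_tables(items)
    out = []
    for item in items:
        f = featurize(item, tables)
        eta = easiness(f, params)
        out.append(CalibratedItem(item.item_id, f, eta, -eta / params.scale))
    return out
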