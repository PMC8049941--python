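"""Respondent simulator and experiment harness.

Synthetic cohorts stand in for human samples: each respondent is a latent
ability drawn from a Normal distribution and answers items with the 4PL
probability implied by their ability and the item's model difficulty.
Respondents are stationary — no learning, fatigue, or practice effects — so
simulated reliability curves reflect the measurement model alone.

Two experiment styles are provided: fixed-form calibration sessions (equal
item counts per level, quasi-random order) for parameter-recovery studies,
and adaptive-test batteries over a range of test lengths for
reliability-versus-length curves (mean standard error, test-retest
correlation from two independent sessions, truth correlation, RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cat import run_session
from .irt import CalibratedItem, ModelParams, response_probability
from .itemgen import ItemBank, PIATItem

__all__ = [
    "Cohort",
    "ExperimentReport",
    "RecoveryConfig",
    "simulate_cohort",
    "simulate_responses",
    "calibration_session_sampler",
    "recovery_experiment",
]


@dataclass(frozen=True)
class Cohort:
    """Synthetic respondents: id -> true latent ability."""

    thetas: Mapping[str, float]
    mean: float
    sd: float
    seed: int

    def __len__(self) -> int:
        return len(self.thetas)

    @property
    def ids(self) -> list[str]:
        return list(self.thetas)

    @property
    def theta_array(self) -> np.ndarray:
        return np.array(list(self.thetas.values()))


def simulate_cohort(n: int, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> Cohort:
    """Draw ``n`` abilities independently from Normal(mean, sd)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    thetas = rng.normal(mean, sd, size=n)
    ids = [f"p{i:05d}" for i in range(n)]
    return Cohort(dict(zip(ids, thetas)), mean, sd, seed)


def simulate_responses(
    cohort: Cohort,
    calibrated_items: Sequence[CalibratedItem],
    params: ModelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli responses of every respondent to every listed item.

    Long format (participant_id, item_id, correct); each response is drawn
    with the 4PL probability at the respondent's true ability.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    b = np.array([it.difficulty for it in calibrated_items])
    item_ids = [it.item_id for it in calibrated_items]
    frames = []
    for pid, theta in cohort.thetas.items():
        p = response_probability(theta, b, params)
        x = (rng.random(len(b)) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {"participant_id": pid, "item_id": item_ids, "correct": x}
            )
        )
    return pd.concat(frames, ignore_index=True)


def calibration_session_sampler(
    bank: ItemBank | Sequence[PIATItem],
    per_level_allocation: Mapping[int, int],
    rng: np.random.Generator | int | None = None,
) -> list[PIATItem]:
    """Quasi-random fixed-form session: a set count of items per level.

    Samples the allocated number of items per level without replacement,
    then shuffles the combined session order.  Default calibration use is
    6 items from each of the 5 levels (30 trials).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_level: dict[int, list[PIATItem]] = {}
    for item in bank:
        by_level.setdefault(item.level, []).append(item)
    session: list[PIATItem] = []
    for level, count in per_level_allocation.items():
        pool = by_level.get(level, [])
        if len(pool) < count:
            raise ValueError(
                f"level {level} has {len(pool)} items, {count} requested"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        session.extend(pool[i] for i in idx)
    order = rng.permutation(len(session))
    return [session[i] for i in order]


@dataclass(frozen=True)
class RecoveryConfig:
    """Settings for a reliability-versus-test-length experiment."""

    cohort_size: int = 200
    test_lengths: tuple[int, ...] = (5, 10, 15, 20, 25)
    seed: int = 0
    cohort_mean: float = 0.0
    cohort_sd: float = 1.0
    retest: bool = True
    compare_random_selection: bool = False
    random_comparison_length: int = 25


@dataclass
class ExperimentReport:
    """Per-test-length reliability metrics plus optional selection baseline."""

    table: pd.DataFrame
    random_baseline: dict | None = None
    config: RecoveryConfig | None = None


def _simulated_responder(theta: float, params: ModelParams, rng: np.random.Generator):
    def respond(item: CalibratedItem) -> int:
        p = response_probability(theta, item.difficulty, params)
        return int(rng.random() < p)

    return respond


def _session_batch(
    calibrated_bank: Sequence[CalibratedItem],
    cohort: Cohort,
    n_items: int,
    params: ModelParams,
    seed: int,
    selector: str = "urry",
) -> pd.DataFrame:
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(cohort))
    for (pid, theta), ss in zip(cohort.thetas.items(), seeds):
        rng = np.random.default_rng(ss)
        session = run_session(
            calibrated_bank,
            _simulated_responder(theta, params, rng),
            n_items=n_items,
            rng=rng,
            params=params,
            selector=selector,
        )
        rows.append(
            {
                "participant_id": pid,
                "true_theta": theta,
                "theta": session.final.theta,
                "se": session.final.se,
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    config: RecoveryConfig,
    calibrated_bank: Sequence[CalibratedItem],
    params: ModelParams | None = None,
) -> ExperimentReport:
    """Adaptive-test reliability as a function of test length.

    For each length, every cohort member takes one CAT session (two
    independent sessions when ``retest`` is on, mirroring a retest visit with
    no time effects); the report rows carry the mean standard error,
    test-retest Pearson correlation, correlation with the generating
    abilities, and RMSE.  Optionally also runs a random-selection baseline
    batch at one length for comparison with adaptive selection.
    """
    params = params or ModelParams()
    cohort = simulate_cohort(
        config.cohort_size, config.cohort_mean, config.cohort_sd, config.seed
    )
    rows = []
    for i, length in enumerate(config.test_lengths):
        s1 = config.seed + 1000 + 2 * i
        first = _session_batch(
            calibrated_bank, cohort, length, params, seed=s1
        )
        row = {
            "test_length": length,
            "mean_se": float(first["se"].mean()),
            "truth_r": float(
                np.corrcoef(first["true_theta"], first["theta"])[0, 1]
            ),
            "rmse": float(
                np.sqrt(np.mean((first["theta"] - first["true_theta"]) ** 2))
            ),
        }
        if config.retest:
            second = _session_batch(
                calibrated_bank, cohort, length, params, seed=s1 + 1
            )
            row["retest_r"] = float(
                np.corrcoef(first["theta"], second["theta"])[0, 1]
            )
        rows.append(row)
    report = ExperimentReport(pd.DataFrame(rows), config=config)
    if config.compare_random_selection:
        L = config.random_comparison_length
        cat_batch = _session_batch(
            calibrated_bank, cohort, L, params, seed=config.seed + 10_001
        )
        rnd_batch = _session_batch(
            calibrated_bank, cohort, L, params,
            seed=config.seed + 10_001, selector="random",
        )
        report.random_baseline = {
            "test_length": L,
            "mean_se_cat": float(cat_batch["se"].mean()),
            "mean_se_random": float(rnd_batch["se"].mean()),
        }
    return report
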