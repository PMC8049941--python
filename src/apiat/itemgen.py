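"""Automatic generation of Pitch Imagery Arrow Task (PIAT) items.

A PIAT trial establishes a major-key tonal context (ascending scale), sounds a
start note (tonic or dominant), then presents a sequence of up/down arrows.
The first ``n_heard`` arrows are accompanied by the corresponding stepwise
scale tones; the remaining ``level`` arrows are silent and must be imagined.
A probe tone is then sounded and the respondent judges whether it matches the
final imagined tone.

All pitch bookkeeping is done in diatonic scale-step offsets from the start
note (offset 0 = start note); conversion to concrete pitches uses integer
semitone (MIDI) indexing with middle C = 60.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable

import numpy as np

__all__ = [
    "KeySignature",
    "ArrowWalk",
    "PIATItem",
    "ItemBank",
    "GenerationConfig",
    "TrialSchedule",
    "ScheduleEvent",
    "KEY_SIGNATURES",
    "GenerationError",
    "degree_to_pitch",
    "generate_walk",
    "assign_probe",
    "generate_bank",
    "trial_schedule",
    "default_calibration_config",
    "level6_extension_config",
    "combined_bank",
]

#: Major-scale interval pattern in semitones (whole/half steps).
MAJOR_SCALE_STEPS = (2, 2, 1, 2, 2, 2, 1)

#: Range bound on scale-step offsets: every note of a trial stays within
#: this many diatonic steps of the start note.
DEFAULT_RANGE_BOUND = 4

#: Display durations in seconds (context scale, start note and hold arrow are
#: long events; ordinary arrows are short).
LONG_EVENT_S = 2.0
SHORT_EVENT_S = 1.0


class GenerationError(RuntimeError):
    """Raised when a requested item cell cannot be populated."""


class ConfigurationError(ValueError):
    """Raised for unknown keys, degrees, or infeasible generation settings."""


@dataclass(frozen=True)
class KeySignature:
    """One of the five admissible major keys, with its tonic pitch."""

    name: str
    tonic_pitch: int

    def scale_pitch(self, scale_index: int) -> int:
        """Pitch of the note ``scale_index`` diatonic steps above the tonic.

        Negative indices descend below the tonic; octaves wrap via the fixed
        major-scale interval pattern.
        """
        octave, degree = divmod(scale_index, 7)
        semis = sum(MAJOR_SCALE_STEPS[:degree])
        return self.tonic_pitch + 12 * octave + semis


#: The five admissible keys; tonics placed in the octave of middle C.
KEY_SIGNATURES: dict[str, KeySignature] = {
    "C": KeySignature("C", 60),
    "C#": KeySignature("C#", 61),
    "D": KeySignature("D", 62),
    "Eb": KeySignature("Eb", 63),
    "E": KeySignature("E", 64),
}

_DEGREE_INDEX = {"tonic": 0, "dominant": 4}


def degree_to_pitch(key: KeySignature | str, start_degree: str, offset: int) -> int:
    """Pitch of the note ``offset`` diatonic steps from the start note.

    Parameters
    ----------
    key:
        A :class:`KeySignature` or one of the admissible key names.
    start_degree:
        ``"tonic"`` or ``"dominant"`` — the scale degree of the start note.
    offset:
        Signed diatonic step offset from the start note; 0 returns the start
        note's own pitch.
    """
    if isinstance(key, str):
        try:
            key = KEY_SIGNATURES[key]
        except KeyError:
            raise ConfigurationError(f"unknown key signature: {key!r}") from None
    if start_degree not in _DEGREE_INDEX:
        raise ConfigurationError(f"unknown start degree: {start_degree!r}")
    if abs(offset) > 8:
        raise ConfigurationError(f"offset {offset} outside the supported +/-8 range")
    return key.scale_pitch(_DEGREE_INDEX[start_degree] + offset)


@dataclass(frozen=True)
class ArrowWalk:
    """The arrow sequence of one trial: heard steps then silent steps.

    Steps are +1 (up) / -1 (down) diatonic moves.  Positions are the running
    offsets from the start note, with the start note at offset 0 (and not
    itself part of ``positions``).
    """

    start_degree: str
    heard_steps: tuple[int, ...]
    silent_steps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(s in (-1, 1) for s in self.heard_steps + self.silent_steps):
            raise ValueError("arrow steps must be +1 or -1")

    @property
    def level(self) -> int:
        return len(self.silent_steps)

    @property
    def n_heard(self) -> int:
        return len(self.heard_steps)

    @property
    def positions(self) -> tuple[int, ...]:
        """Cumulative offsets after each arrow (heard then silent)."""
        return tuple(
            itertools.accumulate(self.heard_steps + self.silent_steps)
        )

    @property
    def heard_positions(self) -> tuple[int, ...]:
        return self.positions[: self.n_heard]

    @property
    def last_heard_offset(self) -> int:
        return self.positions[self.n_heard - 1]

    @property
    def true_final_offset(self) -> int:
        return self.positions[-1]


@lru_cache(maxsize=None)
def _bounded_sign_sequences(length: int, bound: int) -> tuple[tuple[int, ...], ...]:
    """All +/-1 sequences of ``length`` whose running sums stay within ±bound."""
    out = []
    for steps in itertools.product((-1, 1), repeat=length):
        pos = 0
        ok = True
        for s in steps:
            pos += s
            if abs(pos) > bound:
                ok = False
                break
        if ok:
            out.append(steps)
    return tuple(out)


def generate_walk(
    level: int,
    n_heard: int,
    start_degree: str,
    rng: np.random.Generator,
    range_bound: int = DEFAULT_RANGE_BOUND,
) -> ArrowWalk:
    """Sample an arrow walk uniformly among all range-respecting sequences.

    Enumerates every +/-1 sequence of length ``n_heard + level`` whose running
    offsets stay within ``±range_bound`` (cached per length) and draws one
    index from the session generator, so the draw is exactly uniform and
    reproducible per seed.
    """
    if not 1 <= level <= 6:
        raise ConfigurationError(f"level must be in 1..6, got {level}")
    if not 3 <= n_heard <= 5:
        raise ConfigurationError(f"n_heard must be in 3..5, got {n_heard}")
    pool = _bounded_sign_sequences(level + n_heard, range_bound)
    steps = pool[int(rng.integers(len(pool)))]
    return ArrowWalk(start_degree, steps[:n_heard], steps[n_heard:])


class ProbeRetry(RuntimeError):
    """Signals the caller to resample the walk: no admissible probe exists."""


def assign_probe(
    walk: ArrowWalk,
    accuracy: bool,
    rng: np.random.Generator,
    range_bound: int = DEFAULT_RANGE_BOUND,
) -> int:
    """Choose the probe offset for a walk.

    A correct probe equals the true final offset.  An incorrect probe is drawn
    uniformly from offsets 1 or 2 steps away from the true final note,
    excluding the start note (offset 0), the final note itself, and anything
    outside the trial's ±``range_bound``.
    """
    final = walk.true_final_offset
    if accuracy:
        if final == 0:
            raise ProbeRetry("correct probe would be the start note; resample walk")
        return final
    candidates = [
        x
        for x in (final - 2, final - 1, final + 1, final + 2)
        if x != 0 and abs(x) <= range_bound
    ]
    if not candidates:
        raise ProbeRetry("no admissible incorrect probe for this walk")
    return int(rng.choice(candidates))


@dataclass(frozen=True)
class PIATItem:
    """One generated trial."""

    item_id: str
    key: KeySignature
    walk: ArrowWalk
    probe_offset: int
    probe_correct: bool

    @property
    def level(self) -> int:
        return self.walk.level

    @property
    def true_final_offset(self) -> int:
        return self.walk.true_final_offset

    @property
    def probe_pitch(self) -> int:
        return degree_to_pitch(self.key, self.walk.start_degree, self.probe_offset)


@dataclass(frozen=True)
class GenerationConfig:
    """Factor grid for a bank: one item per cell × variation."""

    levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    heard_counts: tuple[int, ...] = (3, 4, 5)
    start_degrees: tuple[str, ...] = ("tonic", "dominant")
    accuracies: tuple[bool, ...] = (True, False)
    keys: tuple[str, ...] = ("C", "C#", "D", "Eb", "E")
    variations: int = 10
    seed: int = 0
    range_bound: int = DEFAULT_RANGE_BOUND
    retry_cap: int = 10_000

    @property
    def n_cells(self) -> int:
        return (
            len(self.levels)
            * len(self.heard_counts)
            * len(self.start_degrees)
            * len(self.accuracies)
            * len(self.keys)
        )

    def cells(self) -> Iterable[tuple[int, int, str, bool, str]]:
        return itertools.product(
            self.levels, self.heard_counts, self.start_degrees,
            self.accuracies, self.keys,
        )


@dataclass
class ItemBank:
    """A generated collection of items plus the config that produced it."""

    items: list[PIATItem]
    config: GenerationConfig

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


def default_calibration_config(seed: int = 0, **overrides) -> GenerationConfig:
    """The calibration-bank grid: 5 levels × 3 heard counts × 2 starts × 2
    accuracies × 5 keys = 300 cells, 10 variations each (3000 items)."""
    return replace(GenerationConfig(seed=seed), **overrides)


def level6_extension_config(seed: int = 1, **overrides) -> GenerationConfig:
    """The harder extension: the same grid restricted to level 6 (600 items)."""
    return replace(GenerationConfig(levels=(6,), seed=seed), **overrides)


def _cell_item(
    level: int,
    n_heard: int,
    start: str,
    accuracy: bool,
    rng: np.random.Generator,
    range_bound: int,
) -> tuple[ArrowWalk, int]:
    while True:
        walk = generate_walk(level, n_heard, start, rng, range_bound)
        try:
            probe = assign_probe(walk, accuracy, rng, range_bound)
        except ProbeRetry:
            continue
        return walk, probe


def generate_bank(config: GenerationConfig) -> ItemBank:
    """Generate one item per (level, heard, start, accuracy, key, variation).

    Variations within a cell are pairwise-distinct (arrow sequence, probe)
    pairs, found by rejection sampling with a retry cap; an exhausted cell
    (fewer distinct valid variations than requested) raises
    :class:`GenerationError` naming the cell.  The result is byte-identical
    across runs for the same config and seed.
    """
    rng = np.random.default_rng(config.seed)
    items: list[PIATItem] = []
    for level, n_heard, start, accuracy, key_name in config.cells():
        key = KEY_SIGNATURES[key_name]
        seen: set[tuple] = set()
        variation = 0
        tries = 0
        while variation < config.variations:
            if tries >= config.retry_cap:
                raise GenerationError(
                    "cell exhausted after "
                    f"{config.retry_cap} tries: level={level} heard={n_heard} "
                    f"start={start} accuracy={accuracy} key={key_name} "
                    f"({variation}/{config.variations} variations found)"
                )
            tries += 1
            walk, probe = _cell_item(
                level, n_heard, start, accuracy, rng, config.range_bound
            )
            sig = (walk.heard_steps, walk.silent_steps, probe)
            if sig in seen:
                continue
            seen.add(sig)
            acc = "T" if accuracy else "F"
            item_id = (
                f"L{level}H{n_heard}{start[0]}{acc}{key_name}v{variation:02d}"
            )
            items.append(PIATItem(item_id, key, walk, probe, accuracy))
            variation += 1
    return ItemBank(items, config)


def combined_bank(
    calibration_seed: int = 0, extension_seed: int = 1, **overrides
) -> ItemBank:
    """The full adaptive-test bank: calibration grid plus level-6 extension."""
    cal = generate_bank(default_calibration_config(calibration_seed, **overrides))
    ext = generate_bank(level6_extension_config(extension_seed, **overrides))
    return ItemBank(cal.items + ext.items, cal.config)


@dataclass(frozen=True)
class ScheduleEvent:
    kind: str  # scale | start-note | heard-arrow | silent-arrow | hold-arrow | probe
    duration: float  # seconds


@dataclass(frozen=True)
class TrialSchedule:
    events: tuple[ScheduleEvent, ...]

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.events)

    @property
    def pre_probe_duration(self) -> float:
        return sum(e.duration for e in self.events if e.kind != "probe")


def trial_schedule(item: PIATItem) -> TrialSchedule:
    """Symbolic timed event list for a trial.

    Context scale and start note display for 2 s each; every heard arrow and
    every non-final silent arrow for 1 s; the final silent arrow carries the
    "hold" cue and displays for 2 s, after which the probe sounds.
    """
    events: list[ScheduleEvent] = [
        ScheduleEvent("scale", LONG_EVENT_S),
        ScheduleEvent("start-note", LONG_EVENT_S),
    ]
    events += [ScheduleEvent("heard-arrow", SHORT_EVENT_S)] * item.walk.n_heard
    events += [ScheduleEvent("silent-arrow", SHORT_EVENT_S)] * (item.level - 1)
    events.append(ScheduleEvent("hold-arrow", LONG_EVENT_S))
    events.append(ScheduleEvent("probe", SHORT_EVENT_S))
    return TrialSchedule(tuple(events))
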