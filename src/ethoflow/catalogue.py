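"""Behavioural-unit catalogue and core domain types for mason-bee mating sequences.

The mating behaviour of male *Osmia cornuta* decomposes into 14 stereotyped
action modules (behavioural units), each with a characteristic duration range
and a position in one of four stages: precopulatory courtship, copulation,
postcopulatory courtship, and the terminal departure.  This module defines the
unit catalogue, the timed-event and sequence containers shared by every other
stage of the pipeline, and a grammar validator that checks an observed or
simulated sequence against the stereotyped structure of the mating flow
ethogram.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Stage(str, Enum):
    """Stage of the mating sequence a behavioural unit belongs to."""

    PRECOPULATORY = "precopulatory"
    COPULATION = "copulation"
    POSTCOPULATORY = "postcopulatory"
    TERMINAL = "terminal"


class Group(str, Enum):
    """Experimental age group of the mating pair.

    REI (Right Emergence Insects) are 107-day-old bees emerging at the natural
    time; AEI (Aged Emergence Insects) are 166-day-old bees whose emergence was
    delayed 59 days at 4 degC.  OTHER covers data with no group label.
    """

    REI = "REI"
    AEI = "AEI"
    OTHER = "OTHER"


#: Copulation unit tokens (the two copulatory acts).
COPULATION_TOKENS = ("long", "short")


@dataclass(frozen=True)
class BehaviouralUnit:
    """One catalogue entry: a stereotyped action module.

    Parameters
    ----------
    token
        Short unique identifier (e.g. ``"pounce"``, ``"ant"``).
    label
        Human-readable name.
    duration_min_s, duration_max_s
        Bounds of the observed duration range, in seconds.  Units whose
        duration was reported as a single value carry a degenerate range;
        instantaneous boundary markers (``end_cop``, ``bye_bye``) carry 0-1 s.
    stage
        Stage of the mating sequence the unit belongs to.
    """

    token: str
    label: str
    duration_min_s: float
    duration_max_s: float
    stage: Stage

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.duration_min_s)
            and math.isfinite(self.duration_max_s)
        ):
            raise ValueError(f"unit {self.token!r}: duration bounds must be finite")
        if self.duration_min_s < 0:
            raise ValueError(f"unit {self.token!r}: duration_min_s must be >= 0")
        if self.duration_max_s < self.duration_min_s:
            raise ValueError(
                f"unit {self.token!r}: duration_max_s < duration_min_s"
            )


def default_catalogue() -> list[BehaviouralUnit]:
    """Return the 14-unit catalogue of the male mating repertoire.

    Duration ranges are transcribed from the behavioural observations, with
    minute values converted to seconds.  ``buzz`` was reported as a point value
    (2 s) and is stored as the degenerate range 2-2 s.  ``end_cop`` and
    ``bye_bye`` are boundary markers with no reported duration and are assigned
    0-1 s.
    """
    S = Stage
    return [
        BehaviouralUnit("pounce", "pounce onto female", 1, 2, S.PRECOPULATORY),
        BehaviouralUnit("sound", "rhythmic sound emission", 30, 35, S.PRECOPULATORY),
        BehaviouralUnit("ant", "antenna motion", 30, 50, S.PRECOPULATORY),
        BehaviouralUnit("buzz", "continuous wing-vibration buzz", 2, 2, S.PRECOPULATORY),
        BehaviouralUnit("abdom", "abdomen stretching", 3, 28, S.PRECOPULATORY),
        BehaviouralUnit("back", "antennae backward", 40, 60, S.PRECOPULATORY),
        BehaviouralUnit("rot", "antenna rotation", 60, 120, S.PRECOPULATORY),
        BehaviouralUnit("long", "long copulation", 60, 120, S.COPULATION),
        BehaviouralUnit("short", "short copulation", 1, 2, S.COPULATION),
        BehaviouralUnit("end_cop", "end of copulation", 0, 1, S.COPULATION),
        BehaviouralUnit("scratch", "scratching", 120, 360, S.POSTCOPULATORY),
        BehaviouralUnit("inact", "inactivity", 600, 1200, S.POSTCOPULATORY),
        BehaviouralUnit("groom", "self-grooming", 120, 180, S.POSTCOPULATORY),
        BehaviouralUnit("bye_bye", "end of mating, male departs", 0, 1, S.TERMINAL),
    ]


def catalogue_by_token(
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> dict[str, BehaviouralUnit]:
    """Index a catalogue by unit token (default catalogue if none given)."""
    units = default_catalogue() if catalogue is None else list(catalogue)
    index = {u.token: u for u in units}
    if len(index) != len(units):
        raise ValueError("catalogue contains duplicate tokens")
    return index


def catalogue_to_json(catalogue: Sequence[BehaviouralUnit] | None = None) -> str:
    """Serialise a catalogue to a JSON document."""
    units = default_catalogue() if catalogue is None else list(catalogue)
    return json.dumps(
        [
            {
                "token": u.token,
                "label": u.label,
                "duration_min_s": u.duration_min_s,
                "duration_max_s": u.duration_max_s,
                "stage": u.stage.value,
            }
            for u in units
        ],
        indent=2,
    )


def catalogue_from_json(text: str) -> list[BehaviouralUnit]:
    """Load a catalogue from its JSON serialisation."""
    return [
        BehaviouralUnit(
            token=d["token"],
            label=d["label"],
            duration_min_s=d["duration_min_s"],
            duration_max_s=d["duration_max_s"],
            stage=Stage(d["stage"]),
        )
        for d in json.loads(text)
    ]


@dataclass
class BehaviouralEvent:
    """One timed occurrence of a behavioural unit.

    ``episode_index`` is the 1-based ordinal of this occurrence of the unit
    within its sequence; repeated units (notably the antenna-motion episodes)
    get strictly increasing indices in time.
    """

    unit_token: str
    start_s: float
    end_s: float
    episode_index: int = 1

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"event {self.unit_token!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )
        if self.episode_index < 1:
            raise ValueError("episode_index must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class MatingSequence:
    """One subject's ordered, timed mating event sequence.

    Events are non-overlapping and time-ordered (half-open intervals
    ``[start_s, end_s)``, so ``end_s`` of one event may equal ``start_s`` of
    the next).  Structural conformance to the mating grammar (first unit
    pounce, etc.) is checked separately by :func:`validate_sequence`.
    """

    subject_id: str
    group: Group = Group.OTHER
    events: list[BehaviouralEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"sequence {self.subject_id!r}: no events")
        seen: dict[str, int] = {}
        for i, ev in enumerate(self.events):
            if i and ev.start_s < self.events[i - 1].end_s:
                raise ValueError(
                    f"sequence {self.subject_id!r}: event {i} "
                    f"({ev.unit_token!r}) overlaps or precedes event {i - 1}"
                )
            prev = seen.get(ev.unit_token, 0)
            if ev.episode_index <= prev:
                raise ValueError(
                    f"sequence {self.subject_id!r}: episode index of "
                    f"{ev.unit_token!r} not strictly increasing at event {i}"
                )
            seen[ev.unit_token] = ev.episode_index

    def tokens(self) -> list[str]:
        """Unit tokens in temporal order."""
        return [ev.unit_token for ev in self.events]

    @property
    def total_duration_s(self) -> float:
        """Total mating duration: last event end minus first event start."""
        return self.events[-1].end_s - self.events[0].start_s


def sequence_from_tokens(
    tokens: Iterable[str],
    subject_id: str = "seq",
    group: Group = Group.OTHER,
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> MatingSequence:
    """Build a timed sequence from bare unit tokens.

    Each event is assigned the midpoint of its unit's catalogue duration
    range (instantaneous markers get their 1 s upper bound), laid out
    contiguously from time 0, with episode indices auto-numbered per unit.
    Useful for turning compact token notation into a full sequence when no
    timing data exist.
    """
    known = catalogue_by_token(catalogue)
    events: list[BehaviouralEvent] = []
    t = 0.0
    counter: dict[str, int] = {}
    for i, tok in enumerate(tokens):
        unit = known.get(tok)
        if unit is None:
            raise ValueError(f"unknown unit token {tok!r} at position {i}")
        dur = (unit.duration_min_s + unit.duration_max_s) / 2.0
        if dur <= 0:
            dur = max(unit.duration_max_s, 1.0)
        counter[tok] = counter.get(tok, 0) + 1
        events.append(BehaviouralEvent(tok, t, t + dur, counter[tok]))
        t += dur
    return MatingSequence(subject_id=subject_id, group=group, events=events)


@dataclass(frozen=True)
class GrammarViolation:
    rule_id: str
    event_position: int
    message: str


@dataclass
class GrammarReport:
    """Result of checking one sequence against the mating grammar."""

    sequence_id: str
    violations: list[GrammarViolation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _structural_ant_count(tokens: list[str]) -> int:
    # Structural antenna episodes: the pre-copula "exit" episode (an ant
    # immediately followed by abdom/back/rot) plus every ant at or after the
    # first copulation unit.  Courtship-loop repeats (ant followed by buzz or
    # sound) are re-entries of the first episode and do not count.
    first_cop = next(
        (i for i, t in enumerate(tokens) if t in COPULATION_TOKENS), len(tokens)
    )
    n = 0
    for i, t in enumerate(tokens):
        if t != "ant":
            continue
        if i >= first_cop:
            n += 1
        elif i + 1 < len(tokens) and tokens[i + 1] in ("abdom", "back", "rot"):
            n += 1
    return n


def validate_sequence(
    seq: MatingSequence,
    strict: bool = False,
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> GrammarReport:
    """Check a sequence against the stereotyped mating grammar.

    Rules encoded (all observed at 100% in the source behavioural data):

    - R1: the sequence begins with ``pounce``.
    - R2: every ``pounce`` is immediately followed by ``sound``.
    - R3: every ``long`` copulation is immediately preceded by ``rot``.
    - R4: ``scratch`` occurs only after an ``end_cop`` that terminates a long
      copulation.
    - R5: after a short copulation's ``end_cop``, the next unit is ``abdom``
      (recovery loop) or ``bye_bye`` (final short copulation).
    - R6: in a single-long mating, at most 4 structural antenna-motion
      episodes occur (the pre-copula exit episode and those during/after
      copulation; courtship-loop repeats are not counted).
    - strict only -- RS: the sequence terminates with ``bye_bye``.

    Violations are reported, never repaired.  An unknown unit token is a hard
    error (the data are malformed, not merely ungrammatical).
    """
    known = catalogue_by_token(catalogue)
    tokens = seq.tokens()
    for i, t in enumerate(tokens):
        if t not in known:
            raise ValueError(
                f"sequence {seq.subject_id!r}: unknown unit token {t!r} "
                f"at position {i}"
            )

    v: list[GrammarViolation] = []

    if tokens[0] != "pounce":
        v.append(GrammarViolation("R1", 0, f"sequence begins with {tokens[0]!r}, not 'pounce'"))

    for i, t in enumerate(tokens):
        if t == "pounce":
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            if nxt != "sound":
                v.append(GrammarViolation("R2", i + 1 if nxt is not None else i,
                                          f"'pounce' followed by {nxt!r}, not 'sound'"))
        elif t == "long":
            if i == 0 or tokens[i - 1] != "rot":
                prev = tokens[i - 1] if i else None
                v.append(GrammarViolation("R3", i,
                                          f"'long' preceded by {prev!r}, not 'rot'"))
        elif t == "scratch":
            # walk back: require end_cop, then the nearest copulation is long
            j = i - 1
            while j >= 0 and tokens[j] == "ant":
                j -= 1
            if j < 0 or tokens[j] != "end_cop":
                v.append(GrammarViolation("R4", i, "'scratch' not preceded by 'end_cop'"))
            else:
                k = j - 1
                while k >= 0 and tokens[k] not in COPULATION_TOKENS:
                    k -= 1
                if k < 0 or tokens[k] != "long":
                    v.append(GrammarViolation(
                        "R4", i, "'scratch' after an end_cop not terminating a long copulation"))
        elif t == "end_cop":
            k = i - 1
            while k >= 0 and tokens[k] not in COPULATION_TOKENS:
                k -= 1
            if k >= 0 and tokens[k] == "short" and i + 1 < len(tokens):
                nxt = tokens[i + 1]
                if nxt not in ("abdom", "bye_bye"):
                    v.append(GrammarViolation(
                        "R5", i + 1,
                        f"after a short copulation's end_cop, {nxt!r} "
                        "instead of 'abdom' or 'bye_bye'"))

    n_long = tokens.count("long")
    n_short = tokens.count("short")
    if n_long == 1 and n_short == 0:
        n_ant = _structural_ant_count(tokens)
        if n_ant > 4:
            v.append(GrammarViolation(
                "R6", len(tokens) - 1,
                f"{n_ant} structural antenna episodes in a single-long mating (max 4)"))

    if strict and tokens[-1] != "bye_bye":
        v.append(GrammarViolation("RS", len(tokens) - 1,
                                  f"sequence ends with {tokens[-1]!r}, not 'bye_bye'"))

    return GrammarReport(sequence_id=seq.subject_id, violations=v)
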