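"""Seeded semi-Markov simulator of mason-bee mating sequences.

Generation is composition-first: the copulation pattern of each mating event
(e.g. "L", "SL", "SSSS") is drawn from the group's composition mixture, then
a timed behavioural sequence realising that pattern is generated.  The
inter-copula loops are not memoryless (the observed compositions cap at four
short copulations), so a free-running first-order chain could not reproduce
the observed composition histogram; the precopulatory courtship, by contrast,
is a genuine stochastic branch structure and is simulated as such with the
observed branch probabilities.

Each behavioural unit's dwell time is drawn uniformly from its catalogue
duration range (the maximum-entropy choice given that only ranges were
observed); events are laid out contiguously from time 0.

Structure realised per pattern symbol:

- first copulation: ``pounce -> sound -> [courtship loop] -> (abdom) ->
  back -> rot -> copulation``; later copulations re-enter at ``sound``.
- after a non-final short: recovery loop ``end_cop -> abdom -> inact -> ant``,
  then back to ``sound``.
- after the final long: ``ant -> end_cop -> scratch -> ant -> inact -> ant ->
  groom -> bye_bye`` (the antenna module thereby recurs four times in a
  single-long mating, as observed).
- after a final short: ``end_cop -> bye_bye`` (the observations do not state
  what, if anything, the male performs before departing after a last short
  copulation; immediate departure is this simulator's explicit convention,
  recorded in batch metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .catalogue import (
    BehaviouralEvent,
    BehaviouralUnit,
    Group,
    MatingSequence,
    catalogue_by_token,
)
from .copulation import CopulationComposition

#: Observed composition mixtures (event counts per pattern) by group.
REI_COMPOSITION_WEIGHTS: dict[str, float] = {"L": 27, "SL": 7}
AEI_COMPOSITION_WEIGHTS: dict[str, float] = {
    "L": 5, "SL": 7, "SSL": 10, "SSS": 5, "SSSS": 5}

#: Observed branch probabilities of the precopulatory courtship.  "ant1"
#: denotes the advance to the exit antenna episode that leads on to abdom;
#: "ant" a repeat of the courtship antenna episode.  after_ant1 exposes the
#: rare bypass variants (exit episode leading straight to back or rot) and
#: after_recovery_abdom the rare direct resumption of a long copulation from
#: abdom; both default to never occurring.
DEFAULT_BRANCH_PROBS: dict[str, dict[str, float]] = {
    "after_pounce": {"sound": 1.0},
    "after_sound": {"ant": 0.96, "buzz": 0.04},
    "after_ant": {"buzz": 0.98, "sound": 0.02},
    "after_buzz": {"sound": 0.11, "ant": 0.04, "ant1": 0.85},
    "after_ant1": {"abdom": 1.0, "back": 0.0, "rot": 0.0},
    "after_rot": {"long": 1.0},
    "after_recovery_abdom": {"inact": 1.0, "long": 0.0},
}


@dataclass
class GroupProfile:
    """Simulator parameterisation for one group.

    ``composition_weights`` need not be normalised; they are the relative
    frequencies of the copulation patterns.  ``dwell_ranges`` entries override
    the catalogue duration range of the named unit.  ``seed`` is the default
    seed used by :func:`simulate_batch` when none is passed explicitly.
    """

    group: str = "OTHER"
    composition_weights: dict[str, float] = field(
        default_factory=lambda: dict(REI_COMPOSITION_WEIGHTS))
    branch_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BRANCH_PROBS.items()})
    dwell_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.composition_weights:
            raise ValueError("composition_weights must not be empty")
        if any(w < 0 for w in self.composition_weights.values()):
            raise ValueError("composition weights must be non-negative")
        if not any(self.composition_weights.values()):
            raise ValueError("composition weights must not all be zero")
        for pattern in self.composition_weights:
            CopulationComposition.from_pattern(pattern)  # validates shape
        for name, dist in self.branch_probs.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"branch {name!r}: outcome probabilities sum to {total}, not 1")
        for token, (lo, hi) in self.dwell_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"dwell range for {token!r} is malformed")


def rei_profile(seed: int | None = None) -> GroupProfile:
    """Default profile of the natural-emergence (REI) group."""
    return GroupProfile(group=Group.REI.value,
                        composition_weights=dict(REI_COMPOSITION_WEIGHTS),
                        seed=seed)


def aei_profile(seed: int | None = None) -> GroupProfile:
    """Default profile of the aged-emergence (AEI) group."""
    return GroupProfile(group=Group.AEI.value,
                        composition_weights=dict(AEI_COMPOSITION_WEIGHTS),
                        seed=seed)


@dataclass
class SimulationBatch:
    """A batch of simulated mating sequences plus its provenance."""

    profile: GroupProfile
    n_events: int
    sequences: list[MatingSequence]
    seed_used: int | None
    metadata: dict = field(default_factory=dict)


def sample_composition(profile: GroupProfile, rng: np.random.Generator) -> str:
    """Draw one copulation pattern from the profile's composition mixture."""
    patterns = sorted(profile.composition_weights)
    weights = np.array([profile.composition_weights[p] for p in patterns],
                       dtype=float)
    return str(rng.choice(patterns, p=weights / weights.sum()))


def _draw(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    outcomes = sorted(dist)
    p = np.array([dist[o] for o in outcomes], dtype=float)
    return str(rng.choice(outcomes, p=p / p.sum()))


def _courtship_tokens(profile: GroupProfile, rng: np.random.Generator) -> list[str]:
    """sound -> (loop over sound/ant/buzz) -> exit ant -> (abdom) -> back -> rot."""
    bp = profile.branch_probs
    tokens = ["sound"]
    state = "sound"
    while True:
        if state == "sound":
            nxt = _draw(bp["after_sound"], rng)
        elif state == "ant":
            nxt = _draw(bp["after_ant"], rng)
        else:  # buzz
            nxt = _draw(bp["after_buzz"], rng)
        if nxt == "ant1":
            break
        tokens.append(nxt)
        state = nxt
    tokens.append("ant")  # the exit antenna episode
    exit_branch = _draw(bp.get("after_ant1", {"abdom": 1.0}), rng)
    if exit_branch == "abdom":
        tokens += ["abdom", "back", "rot"]
    elif exit_branch == "back":
        tokens += ["back", "rot"]
    else:
        tokens += ["rot"]
    return tokens


def _pattern_tokens(
    pattern: str, profile: GroupProfile, rng: np.random.Generator
) -> list[str]:
    CopulationComposition.from_pattern(pattern)  # rejects malformed patterns
    bp = profile.branch_probs
    tokens = ["pounce"]
    for i, sym in enumerate(pattern):
        final = i == len(pattern) - 1
        tokens += _courtship_tokens(profile, rng)
        if sym == "L":
            tokens += ["long", "ant", "end_cop",
                       "scratch", "ant", "inact", "ant", "groom", "bye_bye"]
        elif final:
            tokens += ["short", "end_cop", "bye_bye"]
        else:
            tokens += ["short", "end_cop", "abdom"]
            recovery = _draw(bp.get("after_recovery_abdom", {"inact": 1.0}), rng)
            if recovery == "long":
                # rare observed variant: abdom resumes copulation directly
                tokens += ["long", "ant", "end_cop",
                           "scratch", "ant", "inact", "ant", "groom", "bye_bye"]
                return tokens
            tokens += ["inact", "ant"]
    return tokens


def generate_sequence(
    pattern: str,
    profile: GroupProfile,
    rng: np.random.Generator,
    subject_id: str = "sim",
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> MatingSequence:
    """Generate one timed mating sequence realising a copulation pattern.

    Dwell times are uniform draws from each unit's duration range (profile
    overrides take precedence over the catalogue); events are contiguous from
    time 0 and episode indices number repeated units in order.
    """
    known = catalogue_by_token(catalogue)
    tokens = _pattern_tokens(pattern, profile, rng)
    events: list[BehaviouralEvent] = []
    t = 0.0
    counter: dict[str, int] = {}
    for tok in tokens:
        lo, hi = profile.dwell_ranges.get(
            tok, (known[tok].duration_min_s, known[tok].duration_max_s))
        dur = float(rng.uniform(lo, hi)) if hi > lo else float(hi)
        if dur <= 0:
            dur = 0.5  # instantaneous markers still occupy a nonzero instant
        counter[tok] = counter.get(tok, 0) + 1
        events.append(BehaviouralEvent(tok, t, t + dur, counter[tok]))
        t += dur
    try:
        group = Group(profile.group)
    except ValueError:
        group = Group.OTHER
    return MatingSequence(subject_id=subject_id, group=group, events=events)


def simulate_batch(
    profile: GroupProfile,
    n_events: int,
    seed: int | None = None,
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> SimulationBatch:
    """Simulate a batch of mating events from a group profile.

    Compositions are drawn i.i.d. from the profile mixture; a single RNG
    stream (seeded from ``seed``, falling back to the profile's seed) drives
    the whole batch, so identical profile + seed reproduce the batch exactly.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    seed_used = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed_used)
    sequences = []
    for i in range(n_events):
        pattern = sample_composition(profile, rng)
        sequences.append(generate_sequence(
            pattern, profile, rng,
            subject_id=f"{profile.group}-{i:04d}", catalogue=catalogue))
    return SimulationBatch(
        profile=profile, n_events=n_events, sequences=sequences,
        seed_used=seed_used,
        metadata={
            "seed": seed_used,
            "group": profile.group,
            "final_short_convention": "end_cop -> bye_bye (immediate departure)",
        },
    )


def fixture_counts(group: str) -> list[CopulationComposition]:
    """The observed composition list of a group, for deterministic analysis.

    REI: 27 single-long + 7 short-then-long (34 events).  AEI: 5 L, 7 SL,
    10 SSL, 5 SSS, 5 SSSS (32 events).
    """
    tables = {
        Group.REI.value: [("L", 27), ("SL", 7)],
        Group.AEI.value: [("L", 5), ("SL", 7), ("SSL", 10),
                          ("SSS", 5), ("SSSS", 5)],
    }
    if group not in tables:
        raise ValueError(f"unknown group {group!r}: expected REI or AEI")
    out: list[CopulationComposition] = []
    for pattern, count in tables[group]:
        out.extend(CopulationComposition.from_pattern(pattern)
                   for _ in range(count))
    return out
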