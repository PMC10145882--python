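"""Copulation-composition classification and group statistics.

Each mating event contains one or more copulatory acts of two kinds: a long
copulation (1-2 min), which always terminates the mating, and a short
copulation (a few seconds), after which the male may re-enter the courtship
sequence (inter-copula looping, ICL).  The composition of a mating event is
the temporal string of its copulation types over the alphabet {S, L}, e.g.
"SSL" = short, short, then a final long.

Group statistics summarise a set of mating events: copulation counts, the
long/short ratio, copulation-type frequencies, and the percentage of events
ending with a long copulation.  The complement of the latter is
operationalised as "reproductive failure"; no fertility claim beyond that
arithmetic is encoded.  Percentages and ratios are stored at full precision;
rounding belongs to report rendering only.
"""

from __future__ import annotations

import math
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalogue import COPULATION_TOKENS, MatingSequence


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at the report layer.

    Stored statistics are kept at full precision; this is only for rendering,
    and matches how the headline percentages were rounded in the source data
    (e.g. 31.25 renders as 31.3).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CopulationComposition:
    """Ordered long/short composition of one mating event.

    ``icl_count`` is the number of inter-copula loops: short copulations after
    which the sequence resumed (a final short followed only by the end-of-
    copulation marker and departure does not count).
    """

    pattern: str
    n_short: int
    n_long: int
    ends_with_long: bool
    icl_count: int

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - {"S", "L"}:
            raise ValueError(f"malformed pattern {self.pattern!r}")
        if self.pattern.count("L") > 1 or (
            "L" in self.pattern and not self.pattern.endswith("L")
        ):
            raise ValueError(
                f"pattern {self.pattern!r}: a long copulation terminates the "
                "mating, so at most one 'L' is allowed and it must be final")
        if self.n_short != self.pattern.count("S"):
            raise ValueError("n_short inconsistent with pattern")
        if self.n_long != self.pattern.count("L"):
            raise ValueError("n_long inconsistent with pattern")
        if self.ends_with_long != self.pattern.endswith("L"):
            raise ValueError("ends_with_long inconsistent with pattern")

    @classmethod
    def from_pattern(cls, pattern: str) -> "CopulationComposition":
        """Build a composition from its pattern string alone."""
        n_short = pattern.count("S")
        ends_long = pattern.endswith("L")
        # every short resumes the sequence except a final short
        icl = n_short if ends_long else max(n_short - 1, 0)
        return cls(pattern=pattern, n_short=n_short,
                   n_long=pattern.count("L"),
                   ends_with_long=ends_long, icl_count=icl)


def classify_composition(seq: MatingSequence) -> CopulationComposition:
    """Classify a mating sequence's copulation composition.

    Scans the sequence for copulation units in temporal order.  Raises
    ``ValueError`` if the sequence contains no copulation.
    """
    pattern = "".join(
        "L" if t == "long" else "S"
        for t in seq.tokens()
        if t in COPULATION_TOKENS
    )
    if not pattern:
        raise ValueError(
            f"sequence {seq.subject_id!r}: no copulation observed")
    # icl from the actual event stream: a short counts if any unit other than
    # the end-of-copulation marker or the departure follows it
    tokens = seq.tokens()
    short_positions = [i for i, t in enumerate(tokens) if t == "short"]
    icl = 0
    for i in short_positions:
        tail = [t for t in tokens[i + 1:] if t not in ("end_cop", "bye_bye")]
        if tail:
            icl += 1
    comp = CopulationComposition.from_pattern(pattern)
    if comp.icl_count != icl:
        comp = CopulationComposition(
            pattern=pattern, n_short=comp.n_short, n_long=comp.n_long,
            ends_with_long=comp.ends_with_long, icl_count=icl)
    return comp


@dataclass
class GroupMetrics:
    """Copulation statistics for one group of mating events.

    ``ratio_long_short`` is ``math.inf`` with ``ratio_is_infinite`` set when
    no short copulation occurred.  Frequencies are percentages of all
    copulations; ``pct_end_long`` is the percentage of mating *events* whose
    last copulation is long.  All values are stored at full precision.
    """

    group: str
    n_events: int
    n_long: int
    n_short: int
    ratio_long_short: float
    ratio_is_infinite: bool
    freq_long_pct: float
    freq_short_pct: float
    pct_end_long: float
    composition_histogram: dict[str, int] = field(default_factory=dict)
    mean_duration_by_pattern: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "n_events": self.n_events,
            "n_long": self.n_long,
            "n_short": self.n_short,
            "ratio_long_short": (
                None if self.ratio_is_infinite else self.ratio_long_short),
            "ratio_is_infinite": self.ratio_is_infinite,
            "freq_long_pct": self.freq_long_pct,
            "freq_short_pct": self.freq_short_pct,
            "pct_end_long": self.pct_end_long,
            "composition_histogram": dict(self.composition_histogram),
        }
        if self.mean_duration_by_pattern:
            d["mean_duration_by_pattern_s"] = dict(self.mean_duration_by_pattern)
        return d


def group_metrics(
    events: Sequence[CopulationComposition],
    group: str = "OTHER",
    timings: Mapping[int, float] | Sequence[float] | None = None,
) -> GroupMetrics:
    """Compute the group statistics for a list of mating-event compositions.

    ``timings``, when given, supplies each event's total mating duration in
    seconds (a sequence parallel to ``events`` or a mapping from event index)
    and enables per-pattern mean durations.  The result is invariant under
    permutation of the input (with timings permuted alongside).
    """
    if not events:
        raise ValueError("no mating events supplied")
    n_long = sum(c.n_long for c in events)
    n_short = sum(c.n_short for c in events)
    total = n_long + n_short
    infinite = n_short == 0
    histogram = Counter(c.pattern for c in events)

    mean_by_pattern: dict[str, float] = {}
    if timings is not None:
        if not isinstance(timings, Mapping):
            timings = dict(enumerate(timings))
        acc: dict[str, list[float]] = {}
        for i, c in enumerate(events):
            if i in timings:
                acc.setdefault(c.pattern, []).append(float(timings[i]))
        mean_by_pattern = {
            p: sum(v) / len(v) for p, v in sorted(acc.items())}

    return GroupMetrics(
        group=group,
        n_events=len(events),
        n_long=n_long,
        n_short=n_short,
        ratio_long_short=math.inf if infinite else n_long / n_short,
        ratio_is_infinite=infinite,
        freq_long_pct=100.0 * n_long / total,
        freq_short_pct=100.0 * n_short / total,
        pct_end_long=100.0 * sum(c.ends_with_long for c in events) / len(events),
        composition_histogram=dict(sorted(histogram.items())),
        mean_duration_by_pattern=mean_by_pattern,
    )


@dataclass
class GroupComparison:
    """Comparison of two groups' mating outcomes.

    ``failure_increase_pct`` is the rise in reproductive failure from group a
    to group b, where failure of a group is ``100 - pct_end_long``.
    ``ratio_change`` is b's long/short ratio over a's (``None`` when either
    is infinite).
    """

    group_a: GroupMetrics
    group_b: GroupMetrics
    failure_increase_pct: float
    ratio_change: float | None

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a.to_dict(),
            "group_b": self.group_b.to_dict(),
            "failure_increase_pct": self.failure_increase_pct,
            "ratio_change": self.ratio_change,
        }


def compare_groups(a: GroupMetrics, b: GroupMetrics) -> GroupComparison:
    """Compare two groups: reproductive-failure increase and ratio change."""
    failure_a = 100.0 - a.pct_end_long
    failure_b = 100.0 - b.pct_end_long
    ratio_change = None
    if not a.ratio_is_infinite and not b.ratio_is_infinite and a.ratio_long_short:
        ratio_change = b.ratio_long_short / a.ratio_long_short
    return GroupComparison(
        group_a=a, group_b=b,
        failure_increase_pct=failure_b - failure_a,
        ratio_change=ratio_change,
    )


def duration_summary(
    seqs: Iterable[MatingSequence],
) -> dict[str, tuple[float, float, float, int]]:
    """Total mating duration by composition pattern.

    Each sequence's total duration is last event end minus first event start.
    Returns ``pattern -> (mean_s, min_s, max_s, n)``.
    """
    acc: dict[str, list[float]] = {}
    for seq in seqs:
        pattern = classify_composition(seq).pattern
        acc.setdefault(pattern, []).append(seq.total_duration_s)
    return {
        p: (sum(v) / len(v), min(v), max(v), len(v))
        for p, v in sorted(acc.items())
    }
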