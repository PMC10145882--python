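"""Reading and writing behavioural event logs, token sequences, and ethograms.

Event logs are plain delimited tables (CSV by default), one row per
behavioural event, with times in seconds from mating onset (0-based, half-open
intervals).  A ``frames_24fps`` time unit is supported because the source
material is 24-frame-per-second video; frame counts convert to seconds by
exact division.  Ethogram graphs export to DOT and GraphML.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import pandas as pd
import networkx as nx

from .catalogue import (
    BehaviouralEvent,
    BehaviouralUnit,
    Group,
    MatingSequence,
    catalogue_by_token,
)
from .markov import EthogramGraph


@dataclass(frozen=True)
class EventLogDialect:
    """Column naming and time conventions of a delimited event log.

    ``subject``, ``unit``, ``start`` and ``end`` columns are required in the
    input; ``group`` and ``episode`` are optional (defaulting to OTHER and
    auto-numbering per unit).
    """

    delimiter: str = ","
    subject_col: str = "subject"
    group_col: str = "group"
    unit_col: str = "unit"
    start_col: str = "start_s"
    end_col: str = "end_s"
    episode_col: str = "episode"
    time_unit: str = "seconds"  # "seconds" | "frames_24fps"

    def to_seconds(self, value: float) -> float:
        if self.time_unit == "frames_24fps":
            return value / 24.0
        return value


DEFAULT_DIALECT = EventLogDialect()


def read_event_log(
    source: IO[str] | str,
    dialect: EventLogDialect = DEFAULT_DIALECT,
    catalogue: Sequence[BehaviouralUnit] | None = None,
) -> list[MatingSequence]:
    """Parse a delimited event log into one sequence per subject.

    Events are sorted by start time within each subject; subjects are returned
    in order of first appearance.  Raises ``ValueError`` on a missing required
    column, an unknown unit token, a row whose end precedes its start, or
    overlapping events for a subject (row numbers in error messages are
    1-based data rows, excluding the header).
    """
    if isinstance(source, str):
        source = _io.StringIO(source)
    df = pd.read_csv(source, sep=dialect.delimiter, dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    required = [dialect.subject_col, dialect.unit_col,
                dialect.start_col, dialect.end_col]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"event log is missing required column {col!r}")

    known = catalogue_by_token(catalogue)
    has_group = dialect.group_col in df.columns
    has_episode = dialect.episode_col in df.columns

    rows_by_subject: dict[str, list[tuple[int, BehaviouralEvent]]] = {}
    groups: dict[str, Group] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        subject = str(rec[dialect.subject_col]).strip()
        unit = str(rec[dialect.unit_col]).strip()
        if unit not in known:
            raise ValueError(f"row {pos}: unknown unit token {unit!r}")
        try:
            start = dialect.to_seconds(float(rec[dialect.start_col]))
            end = dialect.to_seconds(float(rec[dialect.end_col]))
        except (TypeError, ValueError):
            raise ValueError(f"row {pos}: non-numeric start/end time") from None
        if end <= start:
            raise ValueError(
                f"row {pos}: end ({end}) does not exceed start ({start}) "
                f"for subject {subject!r}")
        episode = 0
        if has_episode and not pd.isna(rec[dialect.episode_col]):
            episode = int(float(rec[dialect.episode_col]))
        rows_by_subject.setdefault(subject, []).append(
            (pos, BehaviouralEvent(unit, start, end, episode or 1)))
        if has_group and subject not in groups:
            groups[subject] = Group(str(rec[dialect.group_col]).strip())

    sequences = []
    for subject, items in rows_by_subject.items():
        items.sort(key=lambda pr: pr[1].start_s)
        events: list[BehaviouralEvent] = []
        counter: dict[str, int] = {}
        for pos, ev in items:
            if events and ev.start_s < events[-1].end_s:
                raise ValueError(
                    f"row {pos}: event {ev.unit_token!r} overlaps the previous "
                    f"event for subject {subject!r}")
            if not has_episode:
                counter[ev.unit_token] = counter.get(ev.unit_token, 0) + 1
                ev = replace(ev, episode_index=counter[ev.unit_token])
            events.append(ev)
        sequences.append(MatingSequence(
            subject_id=subject,
            group=groups.get(subject, Group.OTHER),
            events=events,
        ))
    return sequences


def write_event_log(
    seqs: Iterable[MatingSequence],
    dialect: EventLogDialect = DEFAULT_DIALECT,
    stream: IO[str] | None = None,
) -> str:
    """Write sequences as a delimited event log; returns the text.

    Times are written in seconds with three decimals, so a write->read round
    trip reproduces tokens, order, episode indices and times to 1 ms.
    """
    out = stream if stream is not None else _io.StringIO()
    d = dialect
    header = [d.subject_col, d.group_col, d.unit_col, d.start_col,
              d.end_col, d.episode_col]
    out.write(d.delimiter.join(header) + "\n")
    for seq in seqs:
        for ev in seq.events:
            out.write(d.delimiter.join([
                seq.subject_id,
                seq.group.value,
                ev.unit_token,
                f"{ev.start_s:.3f}",
                f"{ev.end_s:.3f}",
                str(ev.episode_index),
            ]) + "\n")
    return out.getvalue() if stream is None else ""


def parse_token_sequence(
    text: str, catalogue: Sequence[BehaviouralUnit] | None = None
) -> list[str]:
    """Parse compact token notation ("pounce sound ant" or comma-separated).

    Returns the ordered token list, validated against the catalogue; raises
    ``ValueError`` naming the first unknown token and its 1-based position.
    """
    known = catalogue_by_token(catalogue)
    tokens = [t for t in text.replace(",", " ").split() if t]
    for i, t in enumerate(tokens, start=1):
        if t not in known:
            raise ValueError(f"unknown unit token {t!r} at token {i}")
    return tokens


def _ethogram_digraph(graph: EthogramGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for src, dst, p, cls in graph.edges:
        g.add_edge(src, dst, probability=float(p), percentage_class=int(cls),
                   penwidth=float(cls))
    return g


def export_ethogram(graph: EthogramGraph, format: str = "dot") -> str:
    """Serialise a flow-ethogram graph to DOT or GraphML text.

    Each edge carries the transition probability, its percentage class, and a
    pen width proportional to the class rank (thicker arrow = more probable
    transition), matching the flow-ethogram drawing convention.
    """
    fmt = format.lower()
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(_ethogram_digraph(graph)))
    if fmt != "dot":
        raise ValueError(f"unknown ethogram format {format!r}")
    lines = ["digraph ethogram {", "  rankdir=TB;"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for src, dst, p, cls in graph.edges:
        lines.append(
            f'  "{src}" -> "{dst}" [label="{100 * p:.1f}%", '
            f'probability={p:.6f}, percentage_class={cls}, penwidth={cls}];'
        )
    lines.append("}")
    return "\n".join(lines)
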