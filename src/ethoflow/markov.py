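"""First-order Markov analysis of behavioural sequences.

A behavioural sequence is described by the frequency with which each unit is
immediately followed by each other unit.  The estimator counts adjacent pairs
across a corpus of sequences and row-normalises the counts into a transition
probability matrix; the result feeds the flow-ethogram graph, where arrow
thickness encodes a coarse percentage class of the transition probability.

Dwell times play no role here: the analysis reported for the mating data is
the embedded discrete-time chain (percentages of "followed by"), and the
duration structure lives entirely in the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import json

import numpy as np

from .catalogue import MatingSequence


def indexed_state_label(token: str, episode_index: int) -> str:
    """State label for a unit occurrence in indexed mode.

    The first episode of a unit keeps the bare token; later episodes get the
    episode ordinal appended (``ant``, ``ant2``, ``ant3``, ...), mirroring the
    flow-ethogram convention of distinguishing repeated antenna-motion
    episodes.
    """
    return token if episode_index == 1 else f"{token}{episode_index}"


@dataclass
class TransitionModel:
    """State set with pair counts and row-stochastic transition probabilities.

    ``counts[i, j]`` is the number of times state ``i`` was immediately
    followed by state ``j`` across the corpus.  Rows with at least one
    observed departure are normalised to sum to 1; rows of absorbing states
    (e.g. ``bye_bye``) are all zero.  Unobserved transitions are exactly 0 --
    no smoothing -- so the ethogram shows only observed arrows.
    """

    states: list[str]
    counts: np.ndarray
    probs: np.ndarray
    indexed_mode: bool = False

    def __post_init__(self) -> None:
        n = len(self.states)
        self.counts = np.asarray(self.counts)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.counts.shape != (n, n) or self.probs.shape != (n, n):
            raise ValueError("counts/probs must be square over the state set")
        self._index = {s: i for i, s in enumerate(self.states)}
        if len(self._index) != n:
            raise ValueError("duplicate state labels")

    def state_index(self, state: str) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise ValueError(f"unknown state {state!r}") from None

    def prob(self, src: str, dst: str) -> float:
        """Estimated probability that ``src`` is immediately followed by ``dst``."""
        return float(self.probs[self.state_index(src), self.state_index(dst)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": self.states,
                "counts": self.counts.astype(int).tolist(),
                "probs": self.probs.tolist(),
                "indexed_mode": self.indexed_mode,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionModel":
        d = json.loads(text)
        return cls(
            states=list(d["states"]),
            counts=np.array(d["counts"], dtype=int),
            probs=np.array(d["probs"], dtype=float),
            indexed_mode=bool(d["indexed_mode"]),
        )


def _state_sequences(
    seqs: Iterable[MatingSequence], indexed_mode: bool
) -> list[list[str]]:
    out = []
    for seq in seqs:
        if indexed_mode:
            out.append(
                [indexed_state_label(e.unit_token, e.episode_index) for e in seq.events]
            )
        else:
            out.append(seq.tokens())
    return out


def estimate_transitions(
    seqs: Sequence[MatingSequence], indexed_mode: bool = False
) -> TransitionModel:
    """Estimate the first-order transition model from a corpus of sequences.

    States are ordered by first appearance across the corpus.  In indexed
    mode, repeated units become distinct states by episode index, as in the
    flow ethograms; otherwise bare tokens are used.

    Raises
    ------
    ValueError
        If no sequence contributes a transition (all of length < 2).
    """
    chains = _state_sequences(seqs, indexed_mode)
    if not any(len(c) >= 2 for c in chains):
        raise ValueError("no transitions: every sequence has length < 2")

    states: list[str] = []
    index: dict[str, int] = {}
    for chain in chains:
        for s in chain:
            if s not in index:
                index[s] = len(states)
                states.append(s)

    n = len(states)
    counts = np.zeros((n, n), dtype=np.int64)
    for chain in chains:
        for a, b in zip(chain, chain[1:]):
            counts[index[a], index[b]] += 1

    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return TransitionModel(states=states, counts=counts, probs=probs,
                           indexed_mode=indexed_mode)


def sequence_probability(model: TransitionModel, tokens: Sequence[str]) -> float:
    """Probability of a behavioural sequence under the fitted chain.

    The product over adjacent pairs of the transition probabilities; 0 as soon
    as any step was never observed.  All tokens must be model states and the
    path must contain at least one step.
    """
    if len(tokens) < 2:
        raise ValueError("a sequence probability needs at least two states")
    p = 1.0
    for a, b in zip(tokens, tokens[1:]):
        p *= model.prob(a, b)
        if p == 0.0:
            return 0.0
    return p


#: Upper bounds (inclusive) of the percentage classes used for arrow widths.
_CLASS_BOUNDS = (0.05, 0.25, 0.75)


def percentage_class(p: float) -> int:
    """Map a transition probability to its 1-5 percentage class.

    Classes: 1 for (0, 0.05], 2 for (0.05, 0.25], 3 for (0.25, 0.75],
    4 for (0.75, 1.0), 5 for exactly 1.0.  The binning is a rendering
    convention chosen so that the observed branch percentages (2, 4, 11, 85,
    96, 98, 100) land in visually distinct classes.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    if p == 1.0:
        return 5
    for cls, bound in enumerate(_CLASS_BOUNDS, start=1):
        if p <= bound:
            return cls
    return 4


@dataclass
class EthogramGraph:
    """Flow-ethogram graph: one node per state, one arrow per observed transition."""

    nodes: list[str]
    edges: list[tuple[str, str, float, int]] = field(default_factory=list)
    # edges: (src, dst, probability, percentage_class)


def build_ethogram(model: TransitionModel) -> EthogramGraph:
    """Build the flow-ethogram graph from a transition model.

    Edges exist exactly where the estimated probability is nonzero; each
    carries the probability and its percentage class.
    """
    edges = []
    for i, src in enumerate(model.states):
        for j, dst in enumerate(model.states):
            p = float(model.probs[i, j])
            if p > 0.0:
                edges.append((src, dst, p, percentage_class(p)))
    return EthogramGraph(nodes=list(model.states), edges=edges)
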