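"""Synthetic pass-network generation and canonical test networks.

The random generator emulates the statistical shape of a single-match team
passing matrix: 11-14 nodes, a few hundred completed passes, zero diagonal,
and heterogeneous strengths (a goalkeeper and late substitutes touch the
ball far less than midfielders).  It is a Dirichlet-multinomial model:
sender activity and each sender's receiver preferences are Dirichlet draws,
and the total pass count is allocated multinomially over sender-receiver
pairs.  The single ``concentration`` parameter interpolates from uniform
passing structure (large values) to spiky, few-favoured-targets structure
(small values) - exactly the axis the variability metrics measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_io import PassEvent, ValidationError, WeightedDigraph
from .markov import transition_matrix

GENERATOR_VERSION = "1"

__all__ = [
    "SyntheticSpec",
    "generate",
    "match_activity",
    "canonical_fixtures",
    "simulate_pass_sequence",
    "TruncatedWalkWarning",
]


class TruncatedWalkWarning(UserWarning):
    """A simulated pass sequence reached a node with no outgoing passes."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the random pass-matrix generator.

    n
        Number of nodes (players, including substitutes).  Default 14: a
        starting eleven plus three used substitutes.
    total_passes
        Total completed passes to allocate.  Default 500, a typical
        single-team match volume.
    concentration
        Dirichlet concentration for sender activity and receiver
        preferences; 1.0 gives a flat prior (realistically heterogeneous
        draws), large values approach uniform structure.
    activity
        Optional length-n vector of relative sender activity.  Use small
        entries to emulate a goalkeeper or a late substitute; ``None`` draws
        activity from Dirichlet(concentration).
    seed
        Single integer governing all randomness.
    """

    n: int = 14
    total_passes: int = 500
    concentration: float = 1.0
    activity: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        if self.total_passes < 1:
            raise ValidationError(f"total_passes must be >= 1, got {self.total_passes}")
        if self.concentration <= 0:
            raise ValidationError(f"concentration must be > 0, got {self.concentration}")
        if self.activity is not None:
            act = tuple(float(a) for a in self.activity)
            object.__setattr__(self, "activity", act)
            if len(act) != self.n:
                raise ValidationError(f"activity must have length n={self.n}, got {len(act)}")
            if any(a < 0 for a in act):
                raise ValidationError("activity entries must be >= 0")
            if sum(a > 0 for a in act) < 2:
                raise ValidationError("at least two activity entries must be > 0")


def match_activity(n: int = 14) -> tuple[float, ...]:
    """A fixed match-like sender-activity profile for n >= 12 nodes.

    Node 0 is the goalkeeper (low involvement); the last three nodes are
    substitutes with progressively less playing time; the remaining
    outfield starters share uniform activity.
    """
    if n < 12:
        raise ValidationError(f"match_activity needs n >= 12, got {n}")
    act = [1.0] * n
    act[0] = 0.35
    act[-3], act[-2], act[-1] = 0.45, 0.25, 0.10
    return tuple(act)


def generate(spec: SyntheticSpec) -> WeightedDigraph:
    """Draw one random pass network; fully reproducible from ``spec.seed``.

    The total generated weight equals ``spec.total_passes`` exactly and the
    diagonal is always zero.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.activity is not None:
        a = np.asarray(spec.activity, dtype=float)
        a = a / a.sum()
    else:
        a = rng.dirichlet(np.full(n, spec.concentration))
    # joint sender-receiver probabilities; diagonal structurally zero
    P = np.zeros((n, n))
    for i in range(n):
        prefs = rng.dirichlet(np.full(n - 1, spec.concentration))
        P[i, :i] = a[i] * prefs[:i]
        P[i, i + 1:] = a[i] * prefs[i:]
    counts = rng.multinomial(spec.total_passes, P.ravel()).reshape(n, n)
    labels = tuple(str(i + 1) for i in range(n))
    return WeightedDigraph(labels, counts.astype(float), profile="sports")


def _uniform_complete(n: int) -> WeightedDigraph:
    W = np.ones((n, n)) - np.eye(n)
    return WeightedDigraph(tuple(str(i + 1) for i in range(n)), W)


def canonical_fixtures() -> dict[str, WeightedDigraph]:
    """Named small networks with hand-checkable metric values.

    Includes uniform complete digraphs (n = 3, 4, 8, 16), the 2-cycle, the
    single-arc 2-node graph, in/out stars, and a fixed asymmetric 3x3
    matrix used in oracle tests.
    """
    fixtures: dict[str, WeightedDigraph] = {}
    for n in (3, 4, 8, 16):
        fixtures[f"uniform_complete_{n}"] = _uniform_complete(n)
    fixtures["two_cycle"] = WeightedDigraph(("1", "2"), np.array([[0.0, 1.0], [1.0, 0.0]]))
    fixtures["single_arc"] = WeightedDigraph(("1", "2"), np.array([[0.0, 5.0], [0.0, 0.0]]))
    star = np.zeros((5, 5))
    star[0, 1:] = 1.0  # center sends one pass to each leaf
    fixtures["star_out_5"] = WeightedDigraph(tuple(str(i + 1) for i in range(5)), star)
    fixtures["star_in_5"] = WeightedDigraph(tuple(str(i + 1) for i in range(5)), star.T.copy())
    fixtures["asym_3"] = WeightedDigraph(
        ("1", "2", "3"),
        np.array([[0.0, 3.0, 1.0], [2.0, 0.0, 2.0], [1.0, 1.0, 0.0]]),
    )
    return fixtures


def simulate_pass_sequence(
    G: WeightedDigraph,
    length: int,
    start: int | str,
    seed: int,
) -> list[PassEvent]:
    """Sample a random walk of ``length`` passes on the chain of ``G``.

    Each step draws the receiver from the current holder's transition row.
    If the walk reaches a node with zero out-strength before ``length``
    steps, the sequence truncates there with a :class:`TruncatedWalkWarning`.
    Aggregating a long sequence recovers the transition row proportions.
    """
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    if isinstance(start, str):
        try:
            cur = G.labels.index(start)
        except ValueError:
            raise ValidationError(f"unknown start node {start!r}") from None
    else:
        cur = int(start)
        if not 0 <= cur < G.n:
            raise ValidationError(f"start index {start} out of range for n={G.n}")
    MT = transition_matrix(G)
    if not MT.defined_rows[cur]:
        raise ValidationError(f"start node {G.labels[cur]!r} has zero out-strength")
    rng = np.random.default_rng(seed)
    events: list[PassEvent] = []
    t = 0.0
    for _ in range(length):
        nxt = int(rng.choice(G.n, p=MT.M[cur]))
        events.append(PassEvent(G.labels[cur], G.labels[nxt], t))
        t += 1.0
        cur = nxt
        if not MT.defined_rows[cur]:
            if len(events) < length:
                warnings.warn(
                    f"walk truncated after {len(events)} passes: node "
                    f"{G.labels[cur]!r} has zero out-strength",
                    TruncatedWalkWarning,
                    stacklevel=2,
                )
            break
    return events
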