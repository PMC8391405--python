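"""Markov-chain constructs derived from a weighted digraph.

The transition matrix M of the chain associated with an adjacency matrix W
is the row normalization ``M[i, j] = w_ij / s_i`` where ``s_i`` is node i's
out-strength: the probability that the next pass made by player i goes to
player j.  Rows with zero out-strength (a player who never passed, e.g. a
very late substitute) have no defined conditional distribution; they are
left all-zero and flagged in ``defined_rows``, and the 0 log 0 = 0
convention keeps every downstream entropy finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_io import WeightedDigraph, ValidationError

__all__ = ["TransitionMatrix", "transition_matrix", "k_step", "propagate", "MassLossWarning"]


class MassLossWarning(UserWarning):
    """Probability mass was absorbed by a zero-out-strength node."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix of a weighted digraph plus a defined-row mask.

    Every row with ``defined_rows[i]`` true sums to 1 (within 1e-12); rows
    with false are all-zero.
    """

    M: np.ndarray
    defined_rows: np.ndarray

    @property
    def n(self) -> int:
        return self.M.shape[0]


def transition_matrix(G: WeightedDigraph) -> TransitionMatrix:
    """Row-normalize the adjacency matrix by out-strength.

    Scale invariant: ``transition_matrix(cG) == transition_matrix(G)`` for
    any c > 0.
    """
    s = G.out_strengths()
    defined = s > 0
    M = np.zeros_like(G.W, dtype=float)
    M[defined] = G.W[defined] / s[defined, None]
    return TransitionMatrix(M, defined)


def k_step(MT: TransitionMatrix, k: int) -> np.ndarray:
    """The k-step transition matrix M^k by iterated multiplication.

    Rows remain substochastic; a defined row sums to exactly 1 when no
    undefined row is reachable within k steps.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError(f"k must be a positive integer, got {k!r}")
    P = MT.M.copy()
    for _ in range(k - 1):
        P = P @ MT.M
    return P


def propagate(p0: np.ndarray, MT: TransitionMatrix, k: int) -> np.ndarray:
    """Push a state distribution k steps forward: returns ``p0 @ M^k``.

    Warns with the lost mass when the result sums to less than 1 - 1e-9,
    which happens exactly when an undefined (zero out-strength) row is
    reachable from the support of ``p0`` within k steps.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.ndim != 1 or p0.shape[0] != MT.n:
        raise ValidationError(f"p0 must be a length-{MT.n} vector, got shape {p0.shape}")
    if (p0 < 0).any() or abs(p0.sum() - 1.0) > 1e-9:
        raise ValidationError("p0 must be a probability distribution (nonneg, sum 1)")
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError(f"k must be a positive integer, got {k!r}")
    p = p0.copy()
    for _ in range(k):
        p = p @ MT.M
    lost = 1.0 - p.sum()
    if lost > 1e-9:
        warnings.warn(
            f"propagate: {lost:.6g} of the probability mass reached a node "
            "with zero out-strength and was absorbed",
            MassLossWarning,
            stacklevel=2,
        )
    return p
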