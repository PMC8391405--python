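"""Entropy-based variability rates, indexes, total entropies and capacities.

All quantities are functions of a weighted digraph G with adjacency matrix W
(row = sender, column = receiver), total weight ``L = sum(W)``, out-strength
shares ``p_i = s_i_out / L``, in-strength shares ``q_i = s_i_in / L`` and the
row-stochastic transition matrix ``M = W / s_out`` of the associated Markov
chain.  Logarithms are base 2 (all rates and entropies are in bits) and the
0 log2 0 = 0 convention applies throughout, so zero-strength nodes contribute
0 to every sum.

Node level
    R_out(i) = p_i * H(M[i, :])        rate of passing: the node's share of
                                       activity times the Shannon entropy of
                                       its outgoing pass distribution.
    R_in(i)                            rate of reception, in one of two
                                       formal readings (see below).
    IndR = R / log2 n                  bounded index for cross-network
                                       comparison.

Network level
    RN_out  = sum_i R_out(i)           rate of passing of the network.
    EN_out  = H(p)                     total out-entropy: the entropy of the
                                       transmitter marginal of the joint
                                       distribution w_ij / L.  Dually EN_in
                                       = H(q) on the receiver marginal.
    CN_out  = EN_out - RN_in           capacity of passing (signed);
    CN_in   = EN_in  - RN_out          capacity of reception.
    IndCN   = |CN| / log2 n            capacity index in [0, 1].

Reception variants
    The reception rate substitutes w_ij -> w_ji and m_ij -> m_ji into the
    passing rate.  Two readings of "m_ji" are implemented:

    * ``"literal"`` (default): m_ji is an entry of M itself, so
      ``R_in(i) = q_i * sum_j -M[j, i] log2 M[j, i]`` sums column i of the
      row-stochastic M.  The column is not a probability distribution, so
      CN_out can be negative (the sign behaviour reported for real teams).
    * ``"conditional"``: m_ji is an entry of the transition matrix C of the
      transposed network, ``C[i, j] = w_ji / s_i_in = P(sender j | receiver
      i)``.  Then RN_in = H(X|Y) and CN_out = CN_in = I(X;Y) >= 0, the
      textbook mutual information between transmitter and receiver.

    The variant only affects the in-direction rates; out-rates and both
    marginal entropies are variant-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graph_io import MetricReport, ValidationError, WeightedDigraph
from .markov import transition_matrix

Variant = Literal["literal", "conditional"]
VARIANTS = ("literal", "conditional")

__all__ = [
    "NodeMetrics",
    "NetworkMetrics",
    "node_rate_out",
    "node_rate_in",
    "node_index_out",
    "node_index_in",
    "network_rate_out",
    "network_rate_in",
    "network_index_out",
    "network_index_in",
    "total_entropy_out",
    "total_entropy_in",
    "capacity_out",
    "capacity_in",
    "capacity_index_out",
    "capacity_index_in",
    "full_report",
]


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node passing/reception rates (bits) and their [0, 1] indexes."""

    label: str
    R_out: float
    R_in: float
    IndR_out: float
    IndR_in: float


@dataclass(frozen=True)
class NetworkMetrics:
    """Network-level rates, indexes, total entropies and capacities.

    ``CN_out`` and ``CN_in`` are reported signed; only the capacity indexes
    take the absolute value.  ``L`` is the total weight of the network.
    """

    RN_out: float
    RN_in: float
    IndRN_out: float
    IndRN_in: float
    EN_out: float
    EN_in: float
    CN_out: float
    CN_in: float
    IndCN_out: float
    IndCN_in: float
    L: float


def _xlog2x(x: np.ndarray) -> np.ndarray:
    """Elementwise x * log2(x) with the 0 log2 0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValidationError(f"unknown reception variant {variant!r}; expected one of {VARIANTS}")


def _check_index(G: WeightedDigraph, i: int) -> None:
    if not 0 <= i < G.n:
        raise ValidationError(f"node index {i} out of range for n={G.n}")


def _node_rates_out(G: WeightedDigraph) -> np.ndarray:
    """Vector of R_out(i) = p_i * H(row i of M)."""
    L = G.total_weight
    p = G.out_strengths() / L
    M = transition_matrix(G).M
    row_entropy = -_xlog2x(M).sum(axis=1)
    return p * row_entropy


def _node_rates_in(G: WeightedDigraph, variant: Variant) -> np.ndarray:
    _check_variant(variant)
    L = G.total_weight
    q = G.in_strengths() / L
    if variant == "literal":
        M = transition_matrix(G).M
        col_sum = -_xlog2x(M).sum(axis=0)
        return q * col_sum
    C = transition_matrix(G.transpose()).M
    row_entropy = -_xlog2x(C).sum(axis=1)
    return q * row_entropy


def node_rate_out(G: WeightedDigraph, i: int) -> float:
    """Rate of passing of node i, in bits; 0 when i never passes."""
    _check_index(G, i)
    return float(_node_rates_out(G)[i])


def node_rate_in(G: WeightedDigraph, i: int, variant: Variant = "literal") -> float:
    """Rate of reception of node i, in bits, under the chosen variant."""
    _check_index(G, i)
    return float(_node_rates_in(G, variant)[i])


def node_index_out(G: WeightedDigraph, i: int) -> float:
    """Passing rate of node i divided by log2 n (bounded index)."""
    return node_rate_out(G, i) / np.log2(G.n)


def node_index_in(G: WeightedDigraph, i: int, variant: Variant = "literal") -> float:
    """Reception rate of node i divided by log2 n."""
    return node_rate_in(G, i, variant) / np.log2(G.n)


def network_rate_out(G: WeightedDigraph) -> float:
    """Rate of passing of the network: the sum of all node passing rates."""
    return float(_node_rates_out(G).sum())


def network_rate_in(G: WeightedDigraph, variant: Variant = "literal") -> float:
    """Rate of reception of the network: the sum of all node reception rates."""
    return float(_node_rates_in(G, variant).sum())


def network_index_out(G: WeightedDigraph) -> float:
    return network_rate_out(G) / np.log2(G.n)


def network_index_in(G: WeightedDigraph, variant: Variant = "literal") -> float:
    return network_rate_in(G, variant) / np.log2(G.n)


def total_entropy_out(G: WeightedDigraph) -> float:
    """Total out-entropy EN_out = H(p): entropy of the sender marginal, in bits."""
    p = G.out_strengths() / G.total_weight
    return float(-_xlog2x(p).sum())


def total_entropy_in(G: WeightedDigraph) -> float:
    """Total in-entropy EN_in = H(q): entropy of the receiver marginal, in bits."""
    q = G.in_strengths() / G.total_weight
    return float(-_xlog2x(q).sum())


def capacity_out(G: WeightedDigraph, variant: Variant = "literal") -> float:
    """Capacity of passing CN_out = EN_out - RN_in (signed).

    Under the conditional variant this equals the mutual information
    I(X;Y) >= 0 of the sender-receiver joint distribution; under the literal
    variant it can be negative.
    """
    return total_entropy_out(G) - network_rate_in(G, variant)


def capacity_in(G: WeightedDigraph, variant: Variant = "literal") -> float:
    """Capacity of reception CN_in = EN_in - RN_out (signed)."""
    _check_variant(variant)
    return total_entropy_in(G) - network_rate_out(G)


def capacity_index_out(G: WeightedDigraph, variant: Variant = "literal") -> float:
    """|CN_out| / log2 n, in [0, 1]."""
    return abs(capacity_out(G, variant)) / np.log2(G.n)


def capacity_index_in(G: WeightedDigraph, variant: Variant = "literal") -> float:
    """|CN_in| / log2 n, in [0, 1]."""
    return abs(capacity_in(G, variant)) / np.log2(G.n)


def full_report(
    G: WeightedDigraph,
    variant: Variant = "literal",
    meta: dict | None = None,
) -> MetricReport:
    """Compute every node and network metric in one pass.

    The internal identities hold exactly by construction: RN is the sum of
    the node rates, CN = EN - RN, and every index is the corresponding value
    over log2 n.
    """
    _check_variant(variant)
    log2n = float(np.log2(G.n))
    r_out = _node_rates_out(G)
    r_in = _node_rates_in(G, variant)
    per_node = [
        NodeMetrics(
            label=lab,
            R_out=float(ro),
            R_in=float(ri),
            IndR_out=float(ro) / log2n,
            IndR_in=float(ri) / log2n,
        )
        for lab, ro, ri in zip(G.labels, r_out, r_in)
    ]
    # sum the stored per-node floats so RN == sum(node rates) holds exactly
    RN_out = float(sum(nm.R_out for nm in per_node))
    RN_in = float(sum(nm.R_in for nm in per_node))
    EN_out = total_entropy_out(G)
    EN_in = total_entropy_in(G)
    CN_out = EN_out - RN_in
    CN_in = EN_in - RN_out
    network = NetworkMetrics(
        RN_out=RN_out,
        RN_in=RN_in,
        IndRN_out=RN_out / log2n,
        IndRN_in=RN_in / log2n,
        EN_out=EN_out,
        EN_in=EN_in,
        CN_out=CN_out,
        CN_in=CN_in,
        IndCN_out=abs(CN_out) / log2n,
        IndCN_in=abs(CN_in) / log2n,
        L=G.total_weight,
    )
    full_meta = {"n": G.n, "L": G.total_weight}
    if meta:
        full_meta.update(meta)
    return MetricReport(per_node=per_node, network=network, variant=variant, meta=full_meta)
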