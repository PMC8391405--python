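"""Independent brute-force implementations of every metric formula.

These are written as literal double/triple sums over the joint distribution
w_ij / L with explicit Python loops, deliberately sharing no code with the
package, so that agreement between the two routes is a meaningful check.
"""

import math


def _m(W):
    """Row-stochastic matrix by explicit loops; zero rows stay zero."""
    n = len(W)
    M = [[0.0] * n for _ in range(n)]
    for i in range(n):
        s = sum(W[i][j] for j in range(n))
        if s > 0:
            for j in range(n):
                M[i][j] = W[i][j] / s
    return M


def _plog(x):
    return x * math.log2(x) if x > 0 else 0.0


def total_weight(W):
    return sum(sum(row) for row in W)


def rate_out(W, i):
    """Node passing rate: -sum_j ((sum_j w_ij / L) * m_ij log2 m_ij)."""
    n = len(W)
    L = total_weight(W)
    M = _m(W)
    share = sum(W[i][j] for j in range(n)) / L
    return -sum(share * _plog(M[i][j]) for j in range(n))


def rate_in_literal(W, i):
    """Reception rate, literal substitution w_ij->w_ji, m_ij->m_ji in M."""
    n = len(W)
    L = total_weight(W)
    M = _m(W)
    share = sum(W[j][i] for j in range(n)) / L
    return -sum(share * _plog(M[j][i]) for j in range(n))


def rate_in_conditional(W, i):
    """Reception rate with m-entries from the transposed network's chain."""
    n = len(W)
    L = total_weight(W)
    Wt = [[W[j][i] for j in range(n)] for i in range(n)]
    C = _m(Wt)
    share = sum(W[j][i] for j in range(n)) / L
    return -sum(share * _plog(C[i][j]) for j in range(n))


def _rate_in(W, i, variant):
    return rate_in_literal(W, i) if variant == "literal" else rate_in_conditional(W, i)


def index_out(W, i):
    return rate_out(W, i) / math.log2(len(W))


def index_in(W, i, variant):
    return _rate_in(W, i, variant) / math.log2(len(W))


def network_rate_out(W):
    return sum(rate_out(W, i) for i in range(len(W)))


def network_rate_in(W, variant):
    return sum(_rate_in(W, i, variant) for i in range(len(W)))


def network_index_out(W):
    return network_rate_out(W) / math.log2(len(W))


def network_index_in(W, variant):
    return network_rate_in(W, variant) / math.log2(len(W))


def entropy_out(W):
    """-sum_i sum_j (w_ij/L) log2(sum_j w_ij/L): sender-marginal entropy."""
    n = len(W)
    L = total_weight(W)
    total = 0.0
    for i in range(n):
        row_share = sum(W[i][j] / L for j in range(n))
        if row_share > 0:
            for j in range(n):
                total += (W[i][j] / L) * math.log2(row_share)
    return -total


def entropy_in(W):
    n = len(W)
    return entropy_out([[W[j][i] for j in range(n)] for i in range(n)])


def capacity_out(W, variant):
    return entropy_out(W) - network_rate_in(W, variant)


def capacity_in(W, variant):
    return entropy_in(W) - network_rate_out(W)


def capacity_index_out(W, variant):
    return abs(capacity_out(W, variant)) / math.log2(len(W))


def capacity_index_in(W, variant):
    return abs(capacity_in(W, variant)) / math.log2(len(W))


def mutual_information(W):
    """I(X;Y) by triple loop over the joint p_ij = w_ij / L."""
    n = len(W)
    L = total_weight(W)
    px = [sum(W[i][j] for j in range(n)) / L for i in range(n)]
    py = [sum(W[j][i] for j in range(n)) / L for i in range(n)]
    total = 0.0
    for i in range(n):
        for j in range(n):
            pij = W[i][j] / L
            if pij > 0:
                total += pij * math.log2(pij / (px[i] * py[j]))
    return total
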