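# Methods

## Model

A match (or any observation window) is summarised as a weighted digraph
with `n` nodes and adjacency matrix `W`, `w_ij ≥ 0` the number of directed
interactions (completed passes) from node `i` to node `j`. Row = sender,
column = receiver, fixed everywhere in the package and stated in the CSV
headers. Under the default *sports* validation profile the diagonal must
be zero (no self-passes); a *general* profile admits self-loops, for which
every formula below remains well defined.

All metrics are functions of ratios of weights and are therefore invariant
under `W → cW` (c > 0): they measure the *shape* of the interaction
pattern, not its volume. `L` denotes the total weight, `s_i` / `t_i` the
out/in-strengths, `p_i = s_i / L` and `q_i = t_i / L` the sender and
receiver shares, and `M` the row-stochastic transition matrix
`m_ij = w_ij / s_i` of the Markov chain associated with `W` — the
probability that node i's next pass goes to j.

Node rate of passing: `R_out(i) = −Σ_j p_i · m_ij log2 m_ij
= p_i · H(m_i·)`. The network rate `RN_out = Σ_i R_out(i)` is the
conditional entropy `H(Y|X)` of the receiver given the sender under the
joint distribution `w_ij / L`. Total entropies are the marginals:
`EN_out = H(p)`, `EN_in = H(q)`. Capacities are the differences
`CN_out = EN_out − RN_in` and `CN_in = EN_in − RN_out`, reported signed.
Indexes divide by `log2 n` (the maximum a rate can attain, reached by the
uniform distribution) and, for capacities only, take the absolute value.

## The two reception readings

The reception rate is defined by substituting `w_ij → w_ji` and
`m_ij → m_ji` into the passing rate, and that substitution is genuinely
ambiguous: `m_ji` can denote an entry of `M` itself, or an entry of the
transition matrix of the transposed network. Both are implemented and the
report always records which one produced it.

* **literal** (default): `R_in(i) = q_i · Σ_j (−m_ji log2 m_ji)` sums
  column `i` of `M`. A column of a row-stochastic matrix is not a
  probability distribution, so `RN_in` is not a conditional entropy and
  `CN_out = EN_out − RN_in` can be negative. A negative `CN_out` is
  meaningful under this reading: the team's passing (out) patterns are
  more stable than its receiving (in) patterns. This is the reading
  consistent with published team-level values in which `CN_out` comes out
  negative for one side.
* **conditional**: `R_in(i) = q_i · H(C_i·)` with
  `C_ij = w_ji / t_i = P(sender = j | receiver = i)`. Then
  `RN_in = H(X|Y)` and `CN_out = I(X;Y) ≥ 0`, the textbook mutual
  information between transmitter and receiver. Note `CN_in = EN_in −
  RN_out = H(Y) − H(Y|X) = I(X;Y)` holds under *both* readings, since
  `RN_out` is variant-independent; only the in-direction rates and
  `CN_out` depend on the variant.

The tension between the two readings is left as a documented choice, not
resolved: the conditional one is information-theoretically cleaner, the
literal one reproduces the signed behaviour seen in published team
comparisons, so literal is the default.

## Numerical conventions

* Log base 2 throughout; all rates and entropies in bits.
* `0 · log2 0 = 0` everywhere. A node with zero out-strength (a player
  who never passed, e.g. a stoppage-time substitute) has an undefined
  conditional distribution; its transition row is left all-zero, flagged
  in `defined_rows`, and contributes exactly 0 to every sum. This keeps
  every metric finite without dropping the node.
* The `n` in every `log2 n` denominator is the dimension of the supplied
  matrix — 14 when three substitutes are included — never the number of
  active nodes. Including or excluding inactive nodes therefore changes
  every index, which is why the choice is the caller's, made once when
  building the matrix.
* All computation is in double precision with no intermediate rounding;
  serialization rounds to 15 significant digits, which round-trips
  integer pass counts exactly. Network rates are computed by summing the
  stored per-node values so `RN = Σ_i R(i)` holds exactly, and
  `CN = EN − RN` is exact by construction.
* Matrix powers (`k_step`) use iterated multiplication — `k` is small in
  practice and this avoids eigendecomposition edge cases. `propagate`
  warns with the lost mass when the walk can reach a zero-out-strength
  node.

## Synthetic generator

`generate(SyntheticSpec(...))` emulates the statistical shape of a
single-team, single-match pass matrix with a Dirichlet-multinomial model:
sender activity `a ~ Dirichlet(α)` (or a supplied profile), per-sender
receiver preferences `r_i ~ Dirichlet(α)` over the other `n − 1` nodes,
and a single multinomial allocation of `total_passes` over the joint
`a_i r_ij`. Defaults: `n = 14` (a starting eleven plus three used
substitutes), `total_passes = 500` (a typical single-team match volume),
`concentration α = 1.0` (flat prior — realistically heterogeneous draws;
large α approaches uniform structure, small α gives spiky,
few-favoured-targets structure — precisely the axis the variability
metrics measure). `match_activity(n)` supplies a fixed profile with a
low-involvement goalkeeper and progressively quieter substitutes. One
integer seed governs all randomness and the generator version is logged
for reproducibility.

What the generator does **not** emulate: spatiotemporal structure,
tactical formations, score effects, possession interruptions, or any
within-match nonstationarity. Passing tests on synthetic data therefore
demonstrates correctness of the mathematics and the pipeline, not fidelity
of any football interpretation.

Event logs count only completed passes; how interrupted possessions are
encoded upstream is out of scope here, so an event is always a completed
sender → receiver pair.

## Testing strategy and problem sizes

Every formula is checked against an independent brute-force implementation
written as literal double/triple sums with explicit Python loops
(`tests/oracles.py`), sharing no code with the package; agreement is
asserted at 1e-12 absolute on random graphs with `n` in 3–12. Closed forms
on the uniform complete digraph (`R_out(i) = log2(n−1)/n`,
`RN_out = log2(n−1)`, `EN_out = log2 n`,
`CN_out = log2 n − log2(n−1)`) are asserted exactly for n ∈ {3, 4, 8, 16}.
Bound/identity sweeps use 1,000 Dirichlet-multinomial graphs with
`n ≤ 14`; chain-sampling consistency uses a 30,000-pass walk on the
uniform complete 4-node digraph. These sizes keep the whole suite and the
acceptance script within a few seconds while leaving the stochastic
checks comfortable margins.

## Known limitations

* The `[0, 1]` bound on the *literal* reception index is a theorem only
  for the conditional variant; for the literal one it holds across the
  realistic regime tested (n ≤ 14, match-like structure) but can be
  exceeded by adversarial dense graphs at much larger n, because a column
  sum of `−m log2 m` terms can exceed `log2 n`.
* No significance testing: the metrics are descriptive; differences
  between two teams carry no attached uncertainty.
* No stationary-distribution or ergodicity analysis of the chain; the
  Markov machinery is used only to define conditional pass distributions
  and to sample synthetic sequences.
* Rolling-window / within-match dynamics are out of scope; timestamps on
  events are kept only so callers can window before aggregation.
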