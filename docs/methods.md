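# Methods

## Causal model and primitives

A system at one scale is a row-stochastic TPM over n discrete states
together with an intervention distribution P(C) over causes.  P(C) is
deliberately *not* the observed distribution: it encodes which
counterfactuals/interventions are considered viable.  The default is
uniform — every state of a scale is an equally viable intervention — and is
regenerated at each scale (a macroscale's counterfactuals are its own
states, not re-weighted microstates).  A "stationary" mode is provided in
which P(C) at every scale is the observed long-run law of that scale's own
TPM; for consistent coarse grains this coincides with lumping the
microscale's stationary law, so the two descriptions of interventions agree
across scales.

Per-transition primitives are suff(e, c) = P(e|c) and
nec(e, c) = 1 − P(e|C, ¬c), where P(e|C, ¬c) is the P(C)-mixture of the
rows of all causes other than c, renormalized.  System-wide values weight
each transition by P(C)(c)·P(e|c) — the unique reading under which the
weights form a probability measure over transitions.  Their
information-theoretic generalizations are the determinism coefficient
(P(C)-weighted mean of 1 − H(E|c)/log₂n) and the degeneracy coefficient
(1 − H(E)/log₂n on the effect mixture).  All entropies are base 2.

Combined scores: cp_primitive = suff + nec − 1 and cp_info = determinism +
specificity − 1; the latter equals determinism − degeneracy
("effectiveness") and is the default measure, matching the
determinism-plus-specificity convention used in the walkthrough analyses.
Empirically both scores stay in [0, 1] on every system we generate, but the
sum-minus-1 construction does not obviously guarantee it; values are
reported un-clamped and flagged if they leave the interval, since clamping
would hide model violations.

Edge conventions, chosen where the formulas degenerate:

- n = 1: the lone state is fully sufficient and fully degenerate
  (suff = 1, nec = 0, determinism = 1, degeneracy = 1), so every CP-type
  score and the EI are exactly 0.  One-state scales support no causal
  distinctions.
- necessity with P(C) concentrated entirely on the cause under evaluation
  is undefined and raises rather than guessing.

## Coarse grains and dynamical consistency

A macroscale is a set partition of the state indices; its TPM averages each
block's member rows uniformly and lumps columns,
P(B|A) = (1/|A|)Σ_{i∈A}Σ_{j∈B}P(j|i).  Uniform aggregation matches the
uniform-intervention reading of a macrostate; a stationary-weighted
aggregation is available for observed-distribution analyses.

Consistency is operationalized as lump-vs-evolve agreement: for each
macrostate, start the uniform distribution over its members, evolve t
steps under the micro TPM and lump, versus evolving the lumped point mass
under the macro TPM; the partition is consistent if the largest
total-variation distance over all macrostates and t = 1..horizon is at
most the tolerance (defaults: 1e-9, horizon 3).  At t = 1 the two routes
agree by construction of the macro TPM, so the horizon must exceed 1 to
have any force; horizon 3 already rejects, e.g., partial merges of a
deterministic cycle, while any partition into equivalency classes
(identical rows) is strongly lumpable and passes exactly (error ~1e-16).
This criterion is a documented operational choice; it reduces to weak
lumpability at the uniform prior.

## Paths, endpoints, apportioning

The endpoint of the micro → macro path is the consistent partition with
maximal CP; among ties the one with the most macrostates wins (the point
past which dimensionality reduction stops paying), then the
lexicographically smallest canonical label.  Ties are detected with a
1e-9 tolerance: with floating-point log₂, a 5-block permutation-like
macroscale evaluates to 1 − O(1e-16) while a 2-block one can hit 1.0
exactly, and exact comparison would invert the least-reduction tie-break.

The path itself is the longest chain of consistent scales: one pairwise
block merge per step, choosing at each step the consistent merge with the
largest CP gain (ties lexicographic).  Greedy-by-gain makes contribution
profiles stable and reproducible; the total is path-independent anyway by
telescoping.  If no consistent merge exists before the endpoint is
reached, the path jumps straight to the endpoint and is flagged
`no_full_chain`.  Negative per-step gains are never selected when an
alternative with nonnegative gain exists, but are permitted (and reported)
on user-fixed paths.

The apportionment assigns the microscale its own CP and each subsequent
scale its ΔCP; contributions sum to CP(endpoint) exactly.

Greedy endpoint search (for systems too large to enumerate Bell(n)
partitions; the enumerator guards at n = 10) merges greedily and stops on
diminishing returns: either the best available gain stays below ε
(default 1e-6) for `window` (default 3) consecutive steps, or the gain
ratios ΔCPᵢ₊₁/ΔCPᵢ are all below 1 and strictly decreasing throughout a
window.  The endpoint returned is the last scale whose incoming gain
reached ε.  Small ε and a long window guard against stopping at local
maxima; on all shipped fixture families the greedy endpoint's CP matches
the exhaustive one to 1e-9 (a fixture-level property, not a theorem).

## Emergent complexity

Per-step gains (microscale excluded) are clamped at 0 (with a flag naming
clamped steps), normalized to a distribution p over the L steps, and
summarized as EC = −Σ pᵢ log₂ pᵢ, optionally normalized by log₂(L).
Zero-gain steps contribute zero entropy and, by default, still count
toward L ("include" convention); an "exclude" convention drops them from
both the distribution and the normalizing length, since published EC
values do not pin down which convention produced them.  A path with no
positive gain has no contribution distribution: EC is NaN with profile
`bottom_heavy`, keeping "no emergence" distinct from "all emergence at one
scale" (EC = 0).

Profiles: `top_heavy` if the final step holds the strictly largest gain,
`mesoscale` if an earlier step does (gains within 1e-9 of the maximum
count as tied), `bottom_heavy` if no step dominates and the microscale's
CP exceeds the total gain, else `flat`.  The dominance rule is a
documented constant; the underlying taxonomy is qualitative.

## Benchmark generators

The fixtures module generates the structural families used in tests and
examples; all generators are deterministic given their parameters.

- Block models: block-diagonal, rows identical within a block (equivalency
  classes), uniform over the own block by default.  The two-(4,4)-block
  model has microscale determinism 1/3, degeneracy 0, EI 1 bit; its
  2-state macro is the identity.
- Cycle-plus-block: a deterministic cycle joined with a uniform
  equivalency-class block; the walkthrough system is (4,4) with microscale
  CP 2/3 and CE 1/3.
- Mesoscale variants: one member per block deviates from its equivalency
  class while staying supported on its own block, which preserves
  block-level outflows and hence the endpoint's consistency, and spreads
  CP gains across interior merges.
- Permutation matrices: the fully deterministic, non-degenerate,
  zero-emergence limit.

What these stand-ins do **not** show: they are small (n ≤ 10), block-closed
and noiseless outside their designed structure, so passing tests on them
demonstrates the algebra and the search machinery, not robustness to
empirical TPMs estimated from data.  In particular, because the mesoscale
variant keeps its blocks closed, its endpoint macro TPM is perfectly
deterministic, and the final merge's gain (~0.36) always dominates the
interior steps; the variant therefore raises EC relative to the pure block
model (1.92 vs 1.73 bits under defaults) but still classifies as
`top_heavy` under the dominance rule.  A genuinely interior-peaked profile
requires blocks with cross-block flows, i.e. an endpoint with CP < 1,
which the block-closed generator family cannot produce.

The redistribution sweep moves, at step t of `steps`, a fraction t/steps
of every state's non-self within-block mass onto its self-loop, ending
exactly at the identity permutation.  Tracked at a fixed two-block macro,
the CP gain starts at 2/3 and decreases strictly to 0, while the raw EI
difference is 0 at step 0 and then negative (micro EI rises from 1 to 3
bits against a constant 1-bit macro) — the EI-based analysis therefore
detects no emergence at any step, recorded as `ce1_emergence =
max(0, ei_gain)` alongside the raw `ei_gain`.

The SVD statistic Σᵢσᵢ^α (α ∈ (0, 2], default 1; also reported /n) is a
search-free screening heuristic for dynamical reversibility — n for
permutations, 1 for the uniform matrix, strictly increasing along the
redistribution sweep — and is labeled heuristic in all reports; it is
never used in place of a CP computation.

## Stationary distributions

The "stationary" P(C) mode needs a law for every stochastic matrix,
including reducible and periodic ones, so the solver computes the Cesàro
(time-averaged) limit from a uniform start.  Mechanically it
power-iterates the lazy chain (I + T)/2, which has the same recurrent
classes, within-class stationary laws and absorption probabilities and
hence the same limit, but converges geometrically where direct averaging
converges like 1/T (defaults: per-step tolerance 1e-10, budget 1e5
iterations; the result is verified against πT = π at 1e-8).

## Reports and determinism

Reports are plain dictionaries serialized with stable key order and floats
normalized to 12 significant digits (NaN → null), so identical inputs and
configuration produce byte-identical JSON.  Problem sizes throughout the
examples, tests and the acceptance script are n = 8 systems (Bell(8) =
4140 partitions per exhaustive search), which the package's own exhaustive
machinery handles in well under a second per system.

## Known limitations

- Single-path apportioning only; integrating the full non-commensurate set
  of paths (Möbius/Shapley-style schemes) is out of scope.
- Coarse grains of the state space only: no black-boxing/temporal grouping,
  no higher-order macrostates, no partitions of variables.
- No inference of TPMs from time series; inputs are explicit causal models.
- Exhaustive search is limited by Bell growth (guard at n = 10); beyond
  that only the greedy heuristic and the SVD screen apply, and the greedy
  endpoint is not guaranteed optimal off the shipped fixture families.
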