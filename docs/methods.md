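# Methods

## Model

A signaling game on discrete grids: states `s_i` with prior `p_i`, words
`w_j`, actions `a_k`.  The listener's optimum is honest (`a_L*(s) = s`,
which requires every state value to appear on the action grid); the
speaker's optimum `a_S*(s) ≥ s` is non-decreasing in the state, so the
speaker's desired actions preserve the ranking of states.  Payoffs
decline with the absolute distance of the realized action from each
party's optimum, folded into matrices `D_S`, `D_L` of shape
(actions × states) so that expected payoffs are traces of `P Q D`.
Per-state misalignment is `γ(s) = a_S*(s) − s`; the total
`Γ = 12 Σ p_i γ(s_i)` is integral on the default grids (it counts
quarter-step gaps) and is reported with a warning, unrounded, elsewhere.

On the default grids (states {0, 1/2, 1} equiprobable, three words,
actions {0, 1/4, 1/2, 3/4, 1}) exactly twelve admissible games exist.
Labels I (aligned), IV, V, and VI are fixed by their distinguishing
structure; the remaining numerals are assigned by ascending Γ, then
ascending `a_S*(s_1)`, and should be treated as a convention of this
package rather than a canonical ordering.

## Evolutionary dynamics

* **Selection.** Each generation, every agent's payoff is the
  *per-opponent average* against the relevant population (self excluded
  in symmetric mode), computed in O(N) via averaged opponent matrices —
  an exact identity, by linearity of the trace, not an approximation.
  Fitness is `exp(η Π)`.  The alternative of summing payoffs over
  opponents is preserved behind `payoff_aggregation="sum"`; we default
  to the average because η = 10 is calibrated to O(1) payoffs (on the
  default grids per-opponent payoffs lie in [−1, 0]), whereas a sum over
  N = 100 opponents would drive fitness ratios to numerically degenerate
  extremes.
* **Reproduction.** One multinomial draw of N parents per role per
  generation (classic Wright–Fisher).  Equal fitnesses reduce to neutral
  drift with no special case.  If all fitnesses underflow to zero the
  step aborts with a diagnostic rather than sampling garbage.
* **Learning.** An offspring estimates each parental strategy row from
  k categorical samples and keeps the empirical frequencies, stored as
  exact multiples of 1/k with no smoothing.  Zeros are absorbing under
  learning: this is deliberate, since lexicon loss is driven by unused
  words staying unused.
* **Mutation.** With probability μ per matrix, the offspring's matrix is
  replaced by independent uniform draws from the probability simplex
  (flat Dirichlet rows) — the uniform measure on row-stochastic
  matrices.  In symmetric mode P and Q mutate independently.

Randomness is consumed in a fixed order per generation (parent draws per
role, then learning, then mutation masks, then mutant rows), from one
`numpy` generator seeded per realization; realization r of an ensemble
uses `master_seed + r`.  Trajectories are therefore bit-reproducible,
and ensembles can be sharded by seed range.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 100 per role (asym.), 200 (sym.) | population size |
| η | 10 | selection strength on mean payoff |
| μ | 0.001 | per-matrix mutation probability (study grid: 0.001–0.5) |
| k | 100 | learning samples per row (study grid: 10–10⁴) |
| generations | 5000 | enough for mutation–selection balance at most (k, μ) |
| record_every | 1 (≤1000 gens) else 10 | log thinning only |

Breadth-versus-misalignment and re-ranking analyses use 1000 generations,
where the breadth distribution has already stabilized; per-generation
swap statistics require `record_every = 1`.

## Metrics

* **Lexical breadth**: number of columns of P with positive column sum,
  by exact zero test (finite-k learning produces exact zeros; an
  optional ε exists for matrices round-tripped through lossy formats).
* **Meaning loss**: `1 − Tr(S̄)/3` for speakers and
  `1 − (L̄[1,1] + L̄[2,3] + L̄[3,5])/3` for listeners (1-based), both
  measured against the initial informative language.  A fully scrambled
  population approaches 2/3 and 4/5 respectively; a one-word population
  also reaches 2/3 — equal numbers, very different languages.  The
  listener metric averages the listening matrices Q; this is the only
  dimensionally consistent reading of the two global metrics.
* **Information**: the listener's Bayesian posterior over states given a
  word, and its Kullback–Leibler divergence from the prior, in nats.
  Unused words yield flagged NaN columns (dropped explicitly downstream,
  never silently zeroed).
* **Speaker swaps**: each word's rank value is the mean index of the
  states for which it is the population's most probable word (ties to
  the lowest index); a swap event is a pair of words, ranked in both of
  two consecutive generations, whose order strictly reverses.  This
  deliberately filters argmax churn that does not alter the overall
  ranking; an alternative collapse of simultaneous multi-pair reversals
  to one event is available (`collapse=True`).  Swap metrics operate on
  population-average matrices, not per agent.
* **Listener swaps**: Hamming distance between consecutive per-word
  modal-action tuples.
* **Empirical re-ranking**: the same reversed-pair statistic applied to
  word-frequency time series (TSV), rank-based and hence invariant to
  per-row rescaling; all-zero time points are skipped and logged, and
  only evaluated transitions enter the normalization.

## Innovation experiment

Every `period` (default 500) generations a new word enters: a zero
column in every P, and in every Q a new row placed entirely on the
maximal action — a new term always enters speech with the most extreme
interpretation, mirroring how intensifiers are recruited from words with
severe literal meanings.  Expansion provably changes no payoff at the
instant it occurs (the column is zero, the row unreachable); the new
word spreads only through mutation, which draws on the enlarged simplex
and so uses it almost surely.  An alternative reading, in which each
mutant additionally devotes one random state entirely to the newest word,
is available as `mutation_new_word="forced"`; both readings give
indistinguishable verbosity-class dynamics in our experiments.  Breadth
and meaning-loss metrics remain defined on the original three-word
lexicon during innovation runs; verbosity classes cover the full lexicon.

A caveat established by the acceptance checks: under these dynamics the
*frequency* behaviour of verbose speakers is robust (maximal-verbosity
frequency scales roughly with the mutation rate), but the most verbose
class does **not** dominate the lower non-equilibrium classes in
fitness.  At any instant the population is essentially a mixture of the
adapted two-word class and freshly mutated maximal-verbosity speakers
near the fitness floor; the rare intermediate classes are
selection-filtered descendants of mutants partway back to the adapted
language, and a fresh uniform mutant cannot out-earn such a descendant
against the same listener pool.  Both mutation readings behave this way.

## Static equilibria

Pure Nash profiles of the discrete game are enumerated exhaustively
(3³ × 5³ = 3375 binary profiles) by unilateral best-response checks with
a 10⁻¹² tie tolerance.  Off-path listener rows are part of the profile
and checked like any other row — they carry no payoff, so any action is
weakly optimal there, which is what makes babbling (one word spoken, the
listener answering every word with the prior's best action) a complete
equilibrium profile in every game.  Mixed equilibria are out of scope;
the dynamics explore the mixed space.

The continuum benchmark is the uniform-quadratic cheap-talk model with
constant bias b: an N-interval partition equilibrium exists iff
`2N(N−1)b < 1`, with boundaries `t_i = i/N + 2i(i−N)b` verified against
the boundary-type indifference condition to 10⁻⁹ at construction.  The
three-word ceiling quoted for biases above ≈0.04 is the exact bound
1/24 ≈ 0.0417.

## What the simulations do and do not show

All inputs are generated internally; the simulator *is* the data
generator, and its defaults are the study conditions above.  The
acceptance checks run reduced-scale versions — 10–20 realizations of
1000–1500 generations instead of 1000 realizations of 5000 — which is
ample for trend, bound, and modal-class checks but not for ribbon-level
quantitative reproduction; trend checks therefore use rank correlation
across the twelve games rather than strict group-mean monotonicity,
which at 20 realizations is still noisy at neighbouring Γ values.  The
model abstracts away essentially everything about real language except
the misalignment structure: three states, no syntax, no semantics beyond
a scalar intensity, a single shared misalignment level rather than a
population distribution of them, and no population structure.  The
empirical re-ranking statistic is the bridge to corpus data: it makes
simulated and observed word-rank volatility directly comparable, nothing
more.

## Known limitations

* Roman-numeral labels beyond I/IV/V/VI are a package convention.
* Γ integrality and the meaning-loss/breadth metrics assume the default
  grids; custom grids get real-valued Γ (with a warning) and NaN loss
  metrics.
* Moran dynamics, structured populations, per-agent misalignment
  heterogeneity, and word-death mechanics beyond natural frequency loss
  are not modelled.
* The verbosity-class fitness hierarchy discussed under *Innovation
  experiment* is a negative result of this implementation's dynamics.
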