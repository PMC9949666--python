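# hypersig

Stochastic evolutionary dynamics of signaling games with misaligned
speaker–listener interests.

## The problem

In a sender–receiver (cheap talk) game a speaker observes a graded state
*s*, utters a word *w*, and a listener responds with an action *a*.  When
both parties want the action to match the state, evolution reliably finds
a fully informative language.  Real communication is often *misaligned*:
a begging chick wants a bit more food than its mother's optimum, a job
applicant wants a better offer than their qualifications warrant, and
intensifiers like *so* and *very* exist to extract a stronger response
than the facts support.  `hypersig` simulates finite populations of such
speakers and listeners and tracks what misalignment does to the language:
how many words survive, how much information they carry, how often their
meanings get reshuffled ("recycling"), and what happens when fresh
hyperbolic words are regularly coined ("de-lexicalization").

## The model

States `s ∈ {0, 1/2, 1}` (equiprobable), three words, and actions
`a ∈ {0, 1/4, 1/2, 3/4, 1}`.  The listener's preferred action is honest,
`a_L*(s) = s`; a game is defined by the speaker's preferred action per
state, `a_S*(s) ≥ s`, with per-state misalignment `γ(s) = a_S*(s) − s`
and total misalignment `Γ = 12 Σᵢ pᵢ γ(sᵢ)` (an integer 0–6 on these
grids).  Exactly **twelve** such games exist, labelled I (aligned)
through XII (maximally misaligned).

A speaker is a row-stochastic matrix `P` (states × words), a listener a
row-stochastic `Q` (words × actions).  Payoffs are expected distances to
each party's optimum, computed as traces:

```
Π_S(P, Q) = Tr(P Q D_S),   Π_L(Q, P) = Tr(P Q D_L),
D_S[k,i] = −pᵢ |a_k − a_S*(sᵢ)|,   D_L[k,i] = −pᵢ |a_k − sᵢ|.
```

Populations of N agents per role evolve by a Wright–Fisher process:
fitness `f = exp(η Π)` with selection strength η = 10 on the
per-opponent average payoff, fitness-proportional parent sampling, noisy
parental learning (each strategy row estimated from *k* categorical
samples), and with probability μ, mutation to a uniformly random
strategy matrix.  Both one-population (symmetric, each pair plays both
roles) and two-population (asymmetric speaker/listener) modes are
supported.  A static counterpart — exhaustive pure-Nash enumeration of
the discrete game and Crawford–Sobel partition equilibria of the
uniform-quadratic continuum model — is included for comparison.

## Worked example

```pycon
>>> import hypersig as hs
>>> game = hs.default_catalog().get("V")      # Γ = 2, a_S* = (1/2, 1/2, 1)
>>> cfg = hs.SimConfig(game=game, mode="asymmetric", k=100, mu=0.001,
...                    generations=1000, seed=1)
>>> log = hs.run_realization(cfg)
>>> final = log.frame.iloc[-1]
>>> print(f"final breadth fractions: 1-word {final.breadth1:.2f}, "
...       f"2-word {final.breadth2:.2f}, 3-word {final.breadth3:.2f}")
final breadth fractions: 1-word 0.00, 2-word 1.00, 3-word 0.00
>>> print(f"speaker meaning loss {final.meaning_loss_S:.3f}")
speaker meaning loss 0.333
>>> hs.swap_rate(log, "speaker")
0.0
```

After 1000 generations of Game V every speaker has dropped one of the
three words (2-word fraction 1.00): the word natively tied to the lowest
state is abandoned, because the speaker never wants the weakest action.
One of three diagonal word–state pairings is gone, so the speaker
meaning-loss metric `1 − Tr(S̄)/3` sits at 1/3, and in this realization
no population-level re-ranking of words occurred (swap rate 0).

The same machinery is exposed on the command line:

```bash
hypersig enumerate-games            # the twelve-game catalog
hypersig simulate --game V --mode asymmetric --k 100 --mu 0.001 \
    --generations 1000 --seed 1 --out run.csv
hypersig innovate --game V --k 10 --mu 0.1 --period 500 \
    --generations 1500 --seed 1 --out innov.csv
hypersig cs --bias 0.05             # max partition size 3
hypersig equilibria --game XII      # pure Nash profiles by breadth
hypersig rerank freqs.tsv           # re-ranking rate of an empirical table
```

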