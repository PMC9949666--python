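"""The expanding-lexicon experiment.

Periodically a brand-new word becomes available to the population,
emulating de-lexicalization: the recruitment of a word with a stark
literal meaning into emphatic use.  A new word enters as a zero column in
every speaker matrix (initially unused) and a new row in every listener
matrix that is a point mass on the maximal action -- the most extreme
possible interpretation.  Because the column is zero and the row is
unreachable, no payoff changes at the instant of expansion; the new word
spreads only through mutation, which draws on the enlarged simplex and
therefore uses the new word with probability one.

Speakers are classified by *verbosity* -- the number of available words
they use with positive probability -- and the experiment tracks the
frequency and mean fitness of each verbosity class over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .game_space import ValidationError
from .metrics import lexical_breadth
from .wright_fisher import PopulationState, SimConfig, TrajectoryLog, run_realization

__all__ = [
    "InnovationSchedule",
    "expand_lexicon",
    "verbosity_class",
    "run_innovation_experiment",
]


@dataclass(frozen=True)
class InnovationSchedule:
    """When and how often new words are introduced.

    A new word becomes available every ``period`` generations, starting
    from ``start_words`` (the ordinary initial lexicon), optionally
    capped at ``max_words``.
    """

    period: int = 500
    start_words: int = 3
    max_words: Optional[int] = None

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValidationError("innovation period must be >= 1")
        if self.start_words < 1:
            raise ValidationError("start_words must be >= 1")
        if self.max_words is not None and self.max_words < self.start_words:
            raise ValidationError("max_words must be >= start_words")


def expand_lexicon(population: PopulationState) -> PopulationState:
    """Add one word to every agent's strategy matrices.

    Every speaker matrix gains a zero column and every listener matrix a
    new row that is a point mass on the maximal action.  All payoffs are
    unchanged at the instant of expansion, and row-stochasticity is
    preserved exactly.
    """
    N, I, J = population.P.shape
    K = population.Q.shape[2]
    newP = np.concatenate([population.P, np.zeros((N, I, 1))], axis=2)
    new_row = np.zeros((N, 1, K))
    new_row[:, 0, K - 1] = 1.0
    newQ = np.concatenate([population.Q, new_row], axis=1)
    return PopulationState(
        mode=population.mode, P=newP, Q=newQ, generation=population.generation
    )


def verbosity_class(P) -> int:
    """Number of available words a speaker uses, over the full enlarged lexicon.

    Same exact-zero counting rule as :func:`~hypersig.metrics.lexical_breadth`;
    a mutation-drawn speaker is maximally verbose almost surely.
    """
    return lexical_breadth(P)


def run_innovation_experiment(config: SimConfig) -> TrajectoryLog:
    """Run one realization with scheduled lexicon expansions.

    Requires ``config.innovation`` to be an :class:`InnovationSchedule`.
    The trajectory log gains ``n_words`` plus ``class_freq_n`` and
    ``class_fitness_n`` columns for every verbosity class n; breadth and
    meaning-loss metrics remain defined against the original three-word
    lexicon (the first three speaker columns and first three listener
    rows), since that is the language all agents start from.
    """
    if config.innovation is None:
        raise ValidationError("config.innovation must be an InnovationSchedule")
    return run_realization(config)
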