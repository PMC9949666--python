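"""Strategy representations and variation operators.

A speaker's strategy is a row-stochastic matrix P (states x words); a
listener's is a row-stochastic matrix Q (words x actions).  Variation in
the evolutionary dynamics enters through two operators:

* *mutation* -- a fresh matrix whose rows are drawn independently and
  uniformly from the probability simplex (a flat Dirichlet), the standard
  uniform measure on row-stochastic matrices;
* *parental learning* -- an offspring estimates each parental row from k
  categorical samples, yielding the empirical frequency vector.  Learning
  is unbiased but noisy for finite k, and zero entries stay exactly zero,
  which is what lets unused words be lost from a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game_space import DEFAULT_SPACE, StateActionSpace, ValidationError

__all__ = [
    "SpeakerStrategy",
    "ListenerStrategy",
    "validate_row_stochastic",
    "initial_language",
    "initial_matrices",
    "random_strategy",
    "learn_from_parent",
    "learn_matrix",
]

_TOL = 1e-12


def validate_row_stochastic(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate that ``mat`` is 2-D with nonnegative rows summing to 1."""
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError(f"{name} has negative entries")
    sums = arr.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _TOL):
        raise ValidationError(f"{name} rows must sum to 1 (tol {_TOL})")
    return arr


@dataclass(frozen=True)
class SpeakerStrategy:
    """Row-stochastic speaking table P: P[i, j] = Pr(word j | state i)."""

    P: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", validate_row_stochastic(self.P, "P"))

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def n_words(self) -> int:
        return self.P.shape[1]


@dataclass(frozen=True)
class ListenerStrategy:
    """Row-stochastic listening table Q: Q[j, k] = Pr(action k | word j)."""

    Q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "Q", validate_row_stochastic(self.Q, "Q"))

    @property
    def n_words(self) -> int:
        return self.Q.shape[0]

    @property
    def n_actions(self) -> int:
        return self.Q.shape[1]


def initial_matrices(space: StateActionSpace = DEFAULT_SPACE) -> tuple[np.ndarray, np.ndarray]:
    """The perfectly informative initial language, as raw arrays.

    P is the identity (word j is used for state j with certainty) and Q
    maps each word deterministically to the action equal to its state, so
    that in the absence of variation the optimal honest language is played
    forever.  Requires as many words as states and every state present on
    the action grid.
    """
    I = space.n_states
    if space.n_words != I:
        raise ValidationError(
            "initial language requires n_words == n_states "
            f"(got J={space.n_words}, I={I})"
        )
    P = np.eye(I)
    Q = np.zeros((I, space.n_actions))
    for i, s in enumerate(space.states):
        Q[i, space.action_index(s)] = 1.0
    return P, Q


def initial_language(space: StateActionSpace = DEFAULT_SPACE) -> tuple[SpeakerStrategy, ListenerStrategy]:
    """The perfectly informative initial language as validated strategies."""
    P, Q = initial_matrices(space)
    return SpeakerStrategy(P), ListenerStrategy(Q)


def random_strategy(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform-random row-stochastic matrix of the given shape.

    Each row is independent and uniform on the (cols-1)-simplex, i.e. a
    flat Dirichlet draw; every entry has expectation 1/cols and is
    strictly positive almost surely.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValidationError("shape dimensions must be >= 1")
    if cols == 1:
        return np.ones((rows, 1))
    return rng.dirichlet(np.ones(cols), size=rows)


def learn_from_parent(parent_row: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Learn one strategy row from a parent by k categorical samples.

    Returns the empirical frequency vector of ``k`` draws from
    ``parent_row``.  The estimate is unbiased with per-entry variance
    p(1-p)/k, and entries the parent never uses remain exactly zero.
    """
    if k < 1:
        raise ValidationError("learning parameter k must be >= 1")
    row = np.asarray(parent_row, dtype=float)
    counts = rng.multinomial(int(k), row)
    return counts / float(k)


def learn_matrix(parent: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Apply :func:`learn_from_parent` row by row to a whole matrix."""
    if k < 1:
        raise ValidationError("learning parameter k must be >= 1")
    mat = np.asarray(parent, dtype=float)
    counts = rng.multinomial(int(k), mat)
    return counts / float(k)
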