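"""Static equilibrium analysis.

Two complementary views of the same strategic structure:

* the *discrete* game actually simulated, restricted to pure (binary)
  strategies, where Nash equilibria can be enumerated exhaustively
  (3^3 x 5^3 = 3375 profiles on the default grids); and
* the classical *continuum* cheap-talk model with a uniform state prior
  on [0, 1], quadratic loss, and constant speaker bias b, whose
  equilibria are partitions of the state space into N intervals.  A
  partition of size N exists iff 2 N (N - 1) b < 1, with boundaries

      t_i = i/N + 2 i (i - N) b,

  so the maximum equilibrium lexicon size shrinks as the bias grows --
  e.g. at most three words once b exceeds 1/24 ~ 0.0417.  The babbling
  profile (one word spoken, the listener best-responding to the prior)
  is an equilibrium at every bias and in every discrete game.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .game_space import MisalignmentGame, ValidationError
from .metrics import lexical_breadth

__all__ = [
    "PartitionEquilibrium",
    "cs_max_partition_size",
    "cs_partition",
    "is_pure_nash",
    "enumerate_pure_nash",
    "babbling_profile",
]

_TOL = 1e-12


@dataclass(frozen=True)
class PartitionEquilibrium:
    """An N-interval partition equilibrium of the uniform-quadratic model."""

    bias: float
    steps: int
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.boundaries
        if len(t) != self.steps + 1:
            raise ValidationError("need N+1 boundaries for N steps")
        if abs(t[0]) > _TOL or abs(t[-1] - 1.0) > _TOL:
            raise ValidationError("boundaries must start at 0 and end at 1")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("boundaries must be strictly increasing")


def cs_max_partition_size(b: float) -> int:
    """Largest equilibrium partition size at speaker bias ``b``.

    Returns the largest N with 2 N (N - 1) b < 1 (uniform prior,
    quadratic loss, constant bias).  Diverges as b -> 0, so b must be
    strictly positive; with bias 1/4 or more only babbling (N = 1)
    survives.
    """
    if b <= 0:
        raise ValidationError("bias must be > 0 (the aligned case is unbounded)")
    N = 1
    while 2.0 * (N + 1) * N * b < 1.0:
        N += 1
    return N


def _indifference_residuals(b: float, t: np.ndarray) -> np.ndarray:
    """Boundary-type indifference residuals, an independent check.

    At an interior boundary t_i the speaker of type t_i must be
    indifferent between the receiver actions induced by the two adjacent
    intervals -- the midpoints under a uniform prior and quadratic loss:

        (t_i + b - (t_{i-1}+t_i)/2)^2 = (t_i + b - (t_i+t_{i+1})/2)^2.
    """
    lo = (t[:-2] + t[1:-1]) / 2.0
    hi = (t[1:-1] + t[2:]) / 2.0
    ideal = t[1:-1] + b
    return (ideal - lo) ** 2 - (ideal - hi) ** 2


def cs_partition(b: float, N: int, check_tol: float = 1e-9) -> PartitionEquilibrium:
    """Construct the N-interval partition equilibrium at bias ``b``.

    Boundaries follow the closed form ``t_i = i/N + 2 i (i - N) b`` and
    are verified against the indifference (arbitrage) condition at every
    interior boundary to ``check_tol``.  As b -> 0 the partition becomes
    uniform.  Raises if (b, N) is infeasible.
    """
    if b < 0:
        raise ValidationError("bias must be >= 0")
    if N < 1:
        raise ValidationError("partition size N must be >= 1")
    if b > 0 and N > cs_max_partition_size(b):
        raise ValidationError(f"no partition of size {N} exists at bias {b}")
    i = np.arange(N + 1, dtype=float)
    t = i / N + 2.0 * i * (i - N) * b
    res = _indifference_residuals(b, t)
    if res.size and np.max(np.abs(res)) > check_tol:
        raise ValidationError("indifference condition violated beyond tolerance")
    return PartitionEquilibrium(bias=float(b), steps=int(N), boundaries=tuple(t))


def _as_binary(mat, name: str) -> np.ndarray:
    arr = np.asarray(getattr(mat, "P", getattr(mat, "Q", mat)), dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D")
    if not np.all((arr == 0.0) | (arr == 1.0)) or not np.all(arr.sum(axis=1) == 1.0):
        raise ValidationError(f"{name} must be binary with exactly one 1 per row")
    return arr


def is_pure_nash(P, Q, game: MisalignmentGame, tol: float = _TOL) -> bool:
    """Exhaustive unilateral-deviation check for a pure strategy profile.

    True iff no speaker row can be re-pointed to a different word to
    raise Pi_S given Q, and no listener row to a different action to
    raise Pi_L given P.  Off-path listener rows (words never spoken) are
    checked like any other row; since they carry no payoff, any action is
    weakly optimal there, which is what makes babbling a complete
    equilibrium profile rather than a partial strategy.
    """
    P = _as_binary(P, "P")
    Q = _as_binary(Q, "Q")
    # Speaker: B[i, j] = payoff contribution of pointing state i at word j.
    B = (Q @ game.D_S).T
    chosen_w = np.argmax(P, axis=1)
    if np.any(B[np.arange(B.shape[0]), chosen_w] < B.max(axis=1) - tol):
        return False
    # Listener: C[j, k] = contribution of answering word j with action k.
    C = (game.D_L @ P).T
    chosen_a = np.argmax(Q, axis=1)
    if np.any(C[np.arange(C.shape[0]), chosen_a] < C.max(axis=1) - tol):
        return False
    return True


def babbling_profile(game: MisalignmentGame, word: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """The canonical perfectly uninformative profile.

    The speaker utters ``word`` in every state; the listener answers
    every word with the action that best responds to the prior (the
    action minimizing the expected distance to the state, ties to the
    lowest action).  An equilibrium of every game in the catalog.
    """
    space = game.space
    I, J, K = space.n_states, space.n_words, space.n_actions
    P = np.zeros((I, J))
    P[:, word] = 1.0
    prior_best = int(np.argmax(space.probs @ game.D_L.T))
    Q = np.zeros((J, K))
    Q[:, prior_best] = 1.0
    return P, Q


def enumerate_pure_nash(game: MisalignmentGame) -> list[dict]:
    """All pure-strategy Nash profiles of the discrete game.

    Exhausts every binary (P, Q) profile and keeps those passing
    :func:`is_pure_nash`.  Returns a list of dicts with keys ``P``,
    ``Q``, and ``breadth`` (the number of distinct words spoken).
    """
    space = game.space
    I, J, K = space.n_states, space.n_words, space.n_actions
    eyeJ = np.eye(J)
    eyeK = np.eye(K)
    D_S, D_L = game.D_S, game.D_L
    out = []
    for words in itertools.product(range(J), repeat=I):
        P = eyeJ[list(words)]
        B = None
        C = (D_L @ P).T
        best_a = C.max(axis=1)
        for acts in itertools.product(range(K), repeat=J):
            if np.any(C[np.arange(J), list(acts)] < best_a - _TOL):
                continue
            Q = eyeK[list(acts)]
            B = (Q @ D_S).T
            if np.any(B[np.arange(I), list(words)] < B.max(axis=1) - _TOL):
                continue
            out.append({"P": P, "Q": Q, "breadth": lexical_breadth(P)})
    return out
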