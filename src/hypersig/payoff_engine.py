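"""Payoff and fitness computation via the trace formulas.

When a speaker with strategy P meets a listener with strategy Q in a game
with distance matrices D_S, D_L, the expected payoffs over the stream of
state/word/action draws collapse to matrix traces:

    Pi_S(P, Q) = Tr(P Q D_S),    Pi_L(Q, P) = Tr(P Q D_L).

In the symmetric version of the game each pair of players plays both
roles once, so a player with pair (P, Q) facing (P', Q') earns

    Pi(P, Q | P', Q') = Tr(P Q' D_S) + Tr(P' Q D_L).

Because the trace is linear, the payoff of one agent against a whole
population equals its payoff against the population-average opponent
matrix, which makes the per-generation payoff computation O(N) rather
than O(N^2).  Payoffs are averaged per opponent by default (flag
``aggregation="sum"`` preserves the alternative of summing instead);
on the default grids per-opponent payoffs lie in [-1, 0].

Fitness is exponential in payoff, f = exp(eta * Pi), with eta > 0 the
strength of selection.
"""

from __future__ import annotations

import numpy as np

from .game_space import MisalignmentGame, ValidationError

__all__ = [
    "speaker_payoff",
    "listener_payoff",
    "symmetric_payoff",
    "population_payoffs",
    "fitness",
]


def _mat(x) -> np.ndarray:
    """Accept a raw array or a SpeakerStrategy/ListenerStrategy wrapper."""
    if hasattr(x, "P") and isinstance(getattr(x, "P"), np.ndarray):
        return x.P
    if hasattr(x, "Q") and isinstance(getattr(x, "Q"), np.ndarray):
        return x.Q
    return np.asarray(x, dtype=float)


def _check_shapes(P: np.ndarray, Q: np.ndarray, game: MisalignmentGame) -> None:
    K, I = game.D_S.shape
    if P.shape[0] != I:
        raise ValidationError(f"P has {P.shape[0]} state rows, game has {I} states")
    if P.shape[1] != Q.shape[0]:
        raise ValidationError(
            f"word dimensions differ: P has {P.shape[1]} columns, Q has {Q.shape[0]} rows"
        )
    if Q.shape[1] != K:
        raise ValidationError(f"Q has {Q.shape[1]} action columns, game has {K} actions")


def speaker_payoff(P, Q, game: MisalignmentGame) -> float:
    """Expected speaker payoff Tr(P Q D_S); <= 0, and 0 only at the speaker's ideal."""
    P, Q = _mat(P), _mat(Q)
    _check_shapes(P, Q, game)
    return float(np.trace(P @ Q @ game.D_S))


def listener_payoff(P, Q, game: MisalignmentGame) -> float:
    """Expected listener payoff Tr(P Q D_L); 0 iff the listener always acts at a_L*(s)."""
    P, Q = _mat(P), _mat(Q)
    _check_shapes(P, Q, game)
    return float(np.trace(P @ Q @ game.D_L))


def symmetric_payoff(pair, pair_other, game: MisalignmentGame) -> float:
    """Payoff of pair (P, Q) against (P', Q'), playing each role once.

    Equals ``speaker_payoff(P, Q') + listener_payoff(P', Q)``.
    """
    P, Q = pair
    P2, Q2 = pair_other
    return speaker_payoff(P, Q2, game) + listener_payoff(P2, Q, game)


def population_payoffs(population, game: MisalignmentGame, aggregation: str = "mean"):
    """Per-agent payoffs of a whole population, via averaged opponent matrices.

    Parameters
    ----------
    population
        A :class:`~hypersig.wright_fisher.PopulationState` (any object with
        attributes ``mode``, ``P`` of shape (N, I, J) and ``Q`` of shape
        (N, J, K)).  In asymmetric mode ``P`` holds the speaker population
        and ``Q`` the listener population; in symmetric mode agent ``n``
        holds the pair ``(P[n], Q[n])``.
    aggregation
        ``"mean"`` (default): each agent receives its average payoff per
        opponent.  ``"sum"``: the total over opponents.

    Returns
    -------
    asymmetric mode: ``(speaker_payoffs, listener_payoffs)`` arrays of
    length N.  Symmetric mode: one array of length N, with self-play
    excluded from each agent's opponent set.
    """
    if aggregation not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    P = np.asarray(population.P, dtype=float)
    Q = np.asarray(population.Q, dtype=float)
    if P.ndim != 3 or Q.ndim != 3 or P.shape[0] == 0 or Q.shape[0] == 0:
        raise ValidationError("population must hold nonempty (N, rows, cols) strategy stacks")
    D_S, D_L = game.D_S, game.D_L

    if population.mode == "asymmetric":
        n_listeners = Q.shape[0]
        n_speakers = P.shape[0]
        Q_bar = Q.mean(axis=0)
        P_bar = P.mean(axis=0)
        sp = np.einsum("nij,ji->n", P, Q_bar @ D_S)
        li = np.einsum("njk,kj->n", Q, D_L @ P_bar)
        if aggregation == "sum":
            sp = sp * n_listeners
            li = li * n_speakers
        return sp, li

    if population.mode == "symmetric":
        N = P.shape[0]
        if N < 2:
            raise ValidationError("symmetric play needs at least 2 agents")
        tot_Q = Q.sum(axis=0)
        tot_P = P.sum(axis=0)
        # Tr(P_n (sum_m Q_m) D_S) minus the self term, and symmetrically.
        sp_all = np.einsum("nij,ji->n", P, tot_Q @ D_S)
        li_all = np.einsum("njk,kj->n", Q, D_L @ tot_P)
        self_sp = np.einsum("nij,njk,ki->n", P, Q, D_S)
        self_li = np.einsum("nij,njk,ki->n", P, Q, D_L)
        total = (sp_all - self_sp) + (li_all - self_li)
        if aggregation == "mean":
            total = total / (N - 1)
        return total

    raise ValidationError(f"unknown population mode {population.mode!r}")


def fitness(payoff, eta: float):
    """Exponential fitness f = exp(eta * Pi); strictly positive, increasing in Pi."""
    if eta <= 0:
        raise ValidationError("selection strength eta must be > 0")
    return np.exp(eta * np.asarray(payoff, dtype=float))
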