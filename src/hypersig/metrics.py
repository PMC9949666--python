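"""Summary statistics of the evolving language.

Covers lexical breadth (how many words a speaker uses), population-average
strategy matrices, the global meaning-loss metrics against the initial
informative language, the Bayesian listener posterior and per-word
Kullback-Leibler information, the local re-ranking ("swap") statistics for
speakers and listeners, and the same re-ranking rate computed from an
empirical word-frequency time series.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .game_space import ValidationError

__all__ = [
    "lexical_breadth",
    "breadth_fractions",
    "population_average",
    "meaning_loss_speaker",
    "meaning_loss_listener",
    "listener_posterior",
    "kl_information",
    "speaker_assignment",
    "word_rank_values",
    "speaker_swap_events",
    "listener_swap_events",
    "swap_rate",
    "rerank_rate_from_frequency_table",
]

logger = logging.getLogger(__name__)


def _mat(x) -> np.ndarray:
    if hasattr(x, "P") and isinstance(getattr(x, "P"), np.ndarray):
        return x.P
    if hasattr(x, "Q") and isinstance(getattr(x, "Q"), np.ndarray):
        return x.Q
    return np.asarray(x, dtype=float)


def lexical_breadth(P, epsilon: float = 0.0) -> int:
    """Number of words a speaker uses with positive probability.

    Counts columns of P with column sum strictly greater than ``epsilon``.
    The default is an exact-zero test: finite-k parental learning and
    lexicon expansion produce exact zeros, so no tolerance is needed.  A
    positive ``epsilon`` is available for post-hoc analyses of matrices
    that round-tripped through lossy serialization.
    """
    P = _mat(P)
    return int(np.count_nonzero(P.sum(axis=0) > epsilon))


def breadth_fractions(speakers, n_words: int | None = None, epsilon: float = 0.0) -> np.ndarray:
    """Fraction of speakers using 1, 2, ..., J words.

    ``speakers`` is a stack of speaking matrices of shape (N, I, J).
    Returns an array ``f`` of length J (or ``n_words``) with ``f[b-1]``
    the fraction of speakers of breadth b.  On a fixed J-word lexicon the
    fractions partition the population and sum to 1.
    """
    stack = np.asarray(speakers, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValidationError("speakers must be a nonempty (N, I, J) stack")
    J = n_words if n_words is not None else stack.shape[2]
    breadths = np.count_nonzero(stack.sum(axis=1) > epsilon, axis=1)
    out = np.zeros(J)
    for b in range(1, J + 1):
        out[b - 1] = np.mean(breadths == b)
    return out


def population_average(speakers, listeners) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise population means (S_bar, L_bar) of the strategy stacks.

    The mean of row-stochastic matrices is row-stochastic.
    """
    P = np.asarray(speakers, dtype=float)
    Q = np.asarray(listeners, dtype=float)
    if P.ndim != 3 or Q.ndim != 3 or P.shape[0] == 0 or Q.shape[0] == 0:
        raise ValidationError("expected nonempty (N, rows, cols) stacks")
    return P.mean(axis=0), Q.mean(axis=0)


def meaning_loss_speaker(S_bar) -> float:
    """Global speaker meaning loss 1 - Tr(S_bar)/3.

    Measures how much of the initial language's word-state pairing the
    population retains: 0 for the intact initial language.  Both a fully
    scrambled population (every entry 1/3, the high-mutation limit) and a
    one-word population give the bound 2/3.
    """
    S = np.asarray(S_bar, dtype=float)
    if S.shape != (3, 3):
        raise ValidationError(
            f"speaker meaning loss is defined on the original 3x3 lexicon, got {S.shape}"
        )
    return float(1.0 - np.trace(S) / 3.0)


def meaning_loss_listener(L_bar) -> float:
    """Global listener meaning loss 1 - (L[0,0] + L[1,2] + L[2,4])/3.

    The three entries are the initial language's word-action pairings
    (word x -> action 0, y -> 1/2, z -> 1).  The uniform high-mutation
    limit (every entry 1/5) gives the bound 4/5.
    """
    L = np.asarray(L_bar, dtype=float)
    if L.shape != (3, 5):
        raise ValidationError(
            f"listener meaning loss is defined on the original 3x5 lexicon, got {L.shape}"
        )
    return float(1.0 - (L[0, 0] + L[1, 2] + L[2, 4]) / 3.0)


def listener_posterior(S_bar, p) -> np.ndarray:
    """Bayesian posterior over states given each word, p_L(s_i | w_j).

    Column j of the result is ``p_i S[i,j] / sum_i' p_i' S[i',j]``.
    Columns for words spoken with zero total mass are undefined and are
    returned as NaN (flagged, not raised), so downstream information
    curves can drop them explicitly.
    """
    S = np.asarray(S_bar, dtype=float)
    p = np.asarray(p, dtype=float)
    if S.ndim != 2 or p.shape != (S.shape[0],):
        raise ValidationError("S_bar must be (I, J) and p of length I")
    joint = p[:, None] * S
    mass = joint.sum(axis=0)
    post = np.full_like(joint, np.nan)
    used = mass > 0
    post[:, used] = joint[:, used] / mass[used]
    return post


def kl_information(posterior_column, p) -> float:
    """Kullback-Leibler divergence K_w(p_L(s|w) || p(s)) in nats.

    The information a single word carries about the state: zero when the
    posterior matches the prior (an uninformative word), and at most
    ln(1/p_i) for a point-mass posterior.  Uses the 0*log(0/.) = 0
    convention.  A NaN posterior (an unused word) propagates to NaN.
    """
    q = np.asarray(posterior_column, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(q)):
        return float("nan")
    return float(rel_entr(q, p).sum())


def speaker_assignment(S_bar) -> tuple[int, ...]:
    """Most probable word per state, m(i) = argmax_j S_bar[i, j].

    Ties broken to the lowest word index (np.argmax convention).
    """
    S = np.asarray(S_bar, dtype=float)
    return tuple(int(j) for j in np.argmax(S, axis=1))


def word_rank_values(assignment: tuple[int, ...], n_words: int) -> np.ndarray:
    """Strategic rank value of each word: mean index of states where it is modal.

    Words that are modal for no state are unranked (NaN).  Because states
    are graded, a word modal for low states ranks "weaker" than one modal
    for high states.
    """
    ranks = np.full(n_words, np.nan)
    assign = np.asarray(assignment)
    for w in range(n_words):
        states = np.nonzero(assign == w)[0]
        if states.size:
            ranks[w] = states.mean()
    return ranks


def speaker_swap_events(S_t, S_t1, collapse: bool = False) -> int:
    """Number of word pairs whose strategic ranking reverses between generations.

    Each word's rank value is the mean index of the states for which it is
    the population's most probable word; words modal for no state are
    unranked.  A swap event is a pair of words, ranked in both
    generations, whose relative order strictly reverses.  Mere argmax
    changes that do not alter the overall ranking (e.g. a word leaving the
    ranking) do not count.  With ``collapse=True`` simultaneous multi-pair
    reversals count as a single event.
    """
    S0 = np.asarray(S_t, dtype=float)
    S1 = np.asarray(S_t1, dtype=float)
    if S0.shape != S1.shape:
        raise ValidationError("consecutive averages must share a shape")
    J = S0.shape[1]
    r0 = word_rank_values(speaker_assignment(S0), J)
    r1 = word_rank_values(speaker_assignment(S1), J)
    events = 0
    for a in range(J):
        for b in range(a + 1, J):
            if np.isnan(r0[a]) or np.isnan(r0[b]) or np.isnan(r1[a]) or np.isnan(r1[b]):
                continue
            if (r0[a] - r0[b]) * (r1[a] - r1[b]) < 0:
                events += 1
    if collapse:
        return int(events > 0)
    return events


def listener_swap_events(L_t, L_t1) -> int:
    """Hamming distance between per-word modal actions of consecutive generations."""
    L0 = np.asarray(L_t, dtype=float)
    L1 = np.asarray(L_t1, dtype=float)
    if L0.shape != L1.shape:
        raise ValidationError("consecutive averages must share a shape")
    a0 = np.argmax(L0, axis=1)
    a1 = np.argmax(L1, axis=1)
    return int(np.count_nonzero(a0 != a1))


def swap_rate(trajectory, role: str = "speaker") -> float:
    """Average number of swap events per generation over a trajectory.

    Requires a trajectory recorded at every generation (record_every = 1),
    since the events are defined between consecutive generations.
    """
    if getattr(trajectory, "record_every", None) != 1:
        raise ValidationError("swap_rate requires a trajectory recorded with record_every=1")
    frame = trajectory.frame
    col = {"speaker": "swap_speaker", "listener": "swap_listener"}[role]
    transitions = len(frame) - 1
    if transitions < 1:
        raise ValidationError("need at least 2 recorded generations")
    return float(frame[col].iloc[1:].sum() / transitions)


def _rank_orders(values: np.ndarray) -> np.ndarray:
    """Rank of each word by descending frequency, ties to the lowest index."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return ranks


def rerank_rate_from_frequency_table(table) -> float:
    """Re-ranking events per transition in an empirical word-frequency table.

    ``table`` is a DataFrame (rows = time points, columns = words, cells =
    nonnegative usage frequencies or counts) or a path to a TSV with the
    time label in the first column and word names in the header.  At each
    time point words are ranked by frequency (ties to the lowest column
    index); an event is a pair of words whose rank order strictly reverses
    between consecutive time points.  The statistic is rank-based, hence
    invariant to rescaling any row by a positive constant.  Time points
    with all-zero frequencies are skipped (and logged), and only the
    transitions actually evaluated enter the normalization.

    This is the same statistic as :func:`swap_rate` applied to frequency
    ranks, enabling a direct comparison between simulated signal dynamics
    and corpus-derived intensifier usage series.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", index_col=0)
    values = np.asarray(table, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("frequency table needs at least 2 time points")
    if np.any(values < 0):
        raise ValidationError("frequencies must be nonnegative")
    keep = values.sum(axis=1) > 0
    if not keep.all():
        dropped = np.nonzero(~keep)[0]
        logger.info("skipping %d all-zero time point(s): rows %s", dropped.size, dropped.tolist())
    values = values[keep]
    if values.shape[0] < 2:
        raise ValidationError("fewer than 2 usable time points after dropping all-zero rows")
    ranks = np.vstack([_rank_orders(row) for row in values])
    diffs = ranks[:, :, None] - ranks[:, None, :]          # (T, J, J)
    reversed_pairs = (diffs[:-1] * diffs[1:]) < 0
    events = int(np.triu(reversed_pairs, k=1).sum())
    transitions = values.shape[0] - 1
    return events / transitions
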