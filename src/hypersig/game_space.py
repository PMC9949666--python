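"""State/word/action grids and the catalog of misalignment games.

A signaling game couples a speaker, who observes a graded state ``s_i``,
with a listener who responds to the speaker's word with an action ``a_k``.
The listener's preferred action is honest, ``a_L*(s_i) = s_i``; the speaker
may prefer an exaggerated response ``a_S*(s_i) >= s_i``.  The per-state gap

    gamma(s_i) = a_S*(s_i) - a_L*(s_i) >= 0

and its rescaled, prior-weighted total

    Gamma = 12 * sum_i p_i * gamma(s_i)

grade the conflict of interest between the two roles.  On the default
grids (three equiprobable states {0, 1/2, 1} and five actions
{0, 1/4, 1/2, 3/4, 1}) the factor 12 makes Gamma count the integer number
of quarter-steps separating speaker and listener optima, and exactly
twelve admissible games exist; they are conventionally labelled with
roman numerals I (aligned) through XII (maximally misaligned).

Payoffs decline with the absolute distance of the realized action from
each player's optimum.  These distances are precomputed in the matrices
``D_S`` and ``D_L`` of shape (K actions x I states),

    D_S[k, i] = -p_i * |a_k - a_S*(s_i)|,
    D_L[k, i] = -p_i * |a_k - s_i|,

so that expected payoffs reduce to matrix traces (see ``payoff_engine``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "ValidationError",
    "StateActionSpace",
    "MisalignmentGame",
    "GameCatalog",
    "DEFAULT_SPACE",
    "enumerate_games",
    "default_catalog",
    "total_misalignment",
    "build_distance_matrices",
]


class ValidationError(ValueError):
    """Raised when a space, game, or strategy violates its invariants."""


_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]

# Labels fixed by the textual descriptions of the games: I is the aligned
# game, IV maps two states to the single ideal action 1, V is the only
# Gamma = 2 game whose speaker never wants an action other than 1/2 or 1,
# and VI is the remaining Gamma = 2 game.  All other numerals are assigned
# by ascending Gamma then ascending a_S*(s_1) and are provisional.
_PINNED_LABELS = {
    (0.0, 0.5, 1.0): "I",
    (0.0, 1.0, 1.0): "IV",
    (0.5, 0.5, 1.0): "V",
    (0.25, 0.75, 1.0): "VI",
}


@dataclass(frozen=True)
class StateActionSpace:
    """The discrete grids on which a signaling game is played.

    Parameters
    ----------
    states
        Strictly increasing real state values observed by the speaker.
    state_probs
        Prior probability of each state; nonnegative, summing to 1.
    n_words
        Number of words initially available to the speaker (J).
    actions
        Strictly increasing real action values available to the listener.
        Every state value must appear in the action grid so that the
        listener's honest optimum is realizable.
    """

    states: tuple[float, ...] = (0.0, 0.5, 1.0)
    state_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    n_words: int = 3
    actions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        states = tuple(float(s) for s in self.states)
        actions = tuple(float(a) for a in self.actions)
        probs = tuple(float(p) for p in self.state_probs)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "actions", actions)
        object.__setattr__(self, "state_probs", probs)
        if len(states) == 0 or len(actions) == 0:
            raise ValidationError("states and actions must be nonempty")
        if any(b <= a for a, b in zip(states, states[1:])):
            raise ValidationError("states must be strictly increasing")
        if any(b <= a for a, b in zip(actions, actions[1:])):
            raise ValidationError("actions must be strictly increasing")
        if len(probs) != len(states):
            raise ValidationError("state_probs must match states in length")
        if any(p < 0 for p in probs):
            raise ValidationError("state_probs must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError("state_probs must sum to 1 (tol 1e-12)")
        if int(self.n_words) < 1:
            raise ValidationError("n_words must be >= 1")
        object.__setattr__(self, "n_words", int(self.n_words))
        for s in states:
            if s not in actions:
                raise ValidationError(
                    f"state {s} has no matching action: the listener optimum "
                    "a_L*(s) = s must be realizable"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.state_probs, dtype=float)

    def action_index(self, value: float) -> int:
        """Index of ``value`` in the action grid (exact match)."""
        return self.actions.index(float(value))


DEFAULT_SPACE = StateActionSpace()


@dataclass(frozen=True)
class MisalignmentGame:
    """A signaling game defined by the speaker's preferred action per state.

    ``speaker_opt[i]`` is the action value the speaker would most like the
    listener to take upon state ``states[i]``.  It must lie on the action
    grid, satisfy ``speaker_opt[i] >= states[i]`` (the speaker never wants
    *less* than the true state), and be non-decreasing in the state (the
    speaker's desired action preserves the ranking of states).
    """

    space: StateActionSpace = DEFAULT_SPACE
    speaker_opt: tuple[float, ...] = (0.0, 0.5, 1.0)
    label: str | None = None

    def __post_init__(self) -> None:
        opt = tuple(float(a) for a in self.speaker_opt)
        object.__setattr__(self, "speaker_opt", opt)
        if len(opt) != self.space.n_states:
            raise ValidationError("speaker_opt must assign one action per state")
        for a in opt:
            if a not in self.space.actions:
                raise ValidationError(f"speaker optimum {a} not on the action grid")
        for s, a in zip(self.space.states, opt):
            if a < s:
                raise ValidationError(
                    "speaker optimum must satisfy a_S*(s) >= s (gamma >= 0)"
                )
        if any(b < a for a, b in zip(opt, opt[1:])):
            raise ValidationError("speaker optimum must be non-decreasing in the state")

    @property
    def gamma_per_state(self) -> tuple[float, ...]:
        """gamma(s_i) = a_S*(s_i) - s_i for each state."""
        return tuple(a - s for s, a in zip(self.space.states, self.speaker_opt))

    @cached_property
    def _gamma_raw(self) -> float:
        p = self.space.probs
        return float(12.0 * np.dot(p, self.gamma_per_state))

    @property
    def gamma_integral(self) -> bool:
        return abs(self._gamma_raw - round(self._gamma_raw)) <= 1e-9

    @property
    def Gamma(self) -> int | float:
        """Total rescaled misalignment 12 * sum_i p_i gamma(s_i).

        Integral (and returned as ``int``) on the default grids; on custom
        grids a non-integral value is returned as-is with a warning.
        """
        raw = self._gamma_raw
        if self.gamma_integral:
            return int(round(raw))
        warnings.warn(
            f"total misalignment {raw!r} is not integral on this grid",
            stacklevel=2,
        )
        return raw

    @cached_property
    def D_S(self) -> np.ndarray:
        """Speaker distance matrix, shape (K, I); all entries <= 0."""
        a = np.asarray(self.space.actions)[:, None]            # (K, 1)
        opt = np.asarray(self.speaker_opt)[None, :]            # (1, I)
        D = -self.space.probs[None, :] * np.abs(a - opt)
        D.setflags(write=False)
        return D

    @cached_property
    def D_L(self) -> np.ndarray:
        """Listener distance matrix, shape (K, I); all entries <= 0."""
        a = np.asarray(self.space.actions)[:, None]
        s = np.asarray(self.space.states)[None, :]
        D = -self.space.probs[None, :] * np.abs(a - s)
        D.setflags(write=False)
        return D

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" {self.label}" if self.label else ""
        return f"<Game{lab} a_S*={self.speaker_opt} Gamma={self._gamma_raw:g}>"


def total_misalignment(game: MisalignmentGame) -> int | float:
    """Return the rescaled total misalignment Gamma of ``game``."""
    return game.Gamma


def build_distance_matrices(game: MisalignmentGame) -> tuple[np.ndarray, np.ndarray]:
    """Return the pair (D_S, D_L) of payoff-distance matrices."""
    return game.D_S, game.D_L


@dataclass(frozen=True)
class GameCatalog:
    """Ordered collection of all admissible games on one space."""

    games: tuple[MisalignmentGame, ...]

    def __len__(self) -> int:
        return len(self.games)

    def __iter__(self):
        return iter(self.games)

    def __getitem__(self, idx):
        return self.games[idx]

    def get(self, label: str) -> MisalignmentGame:
        """Look a game up by its roman-numeral label."""
        for g in self.games:
            if g.label == label:
                return g
        raise KeyError(f"no game labelled {label!r}")

    @property
    def gammas(self) -> tuple[int | float, ...]:
        return tuple(g.Gamma for g in self.games)

    def by_gamma(self, gamma) -> list[MisalignmentGame]:
        return [g for g in self.games if g.Gamma == gamma]


def enumerate_games(space: StateActionSpace = DEFAULT_SPACE) -> GameCatalog:
    """Enumerate every admissible misalignment game on ``space``.

    An admissible game is a map a_S*: states -> actions with
    a_S*(s_i) >= s_i for every state and a_S* non-decreasing.  On the
    default grids there are exactly twelve such games.  The catalog is
    ordered by ascending Gamma, then ascending speaker-optimum tuple;
    roman-numeral labels are attached with I, IV, V, VI pinned to the
    textually identified games and the rest assigned in catalog order.
    """
    if not isinstance(space, StateActionSpace):
        raise ValidationError("space must be a StateActionSpace")
    games = []
    for opt in itertools.product(space.actions, repeat=space.n_states):
        if any(b < a for a, b in zip(opt, opt[1:])):
            continue
        if any(a < s for s, a in zip(space.states, opt)):
            continue
        games.append(MisalignmentGame(space=space, speaker_opt=opt))
    games.sort(key=lambda g: (g._gamma_raw, g.speaker_opt))

    maps_present = {g.speaker_opt for g in games}
    pinned = {m: lab for m, lab in _PINNED_LABELS.items() if m in maps_present}
    reserved = set(pinned.values())
    sequence = (r for r in _ROMAN if r not in reserved)
    labelled = []
    for g in games:
        label = pinned.get(g.speaker_opt)
        if label is None:
            label = next(sequence, None)
        labelled.append(MisalignmentGame(space=space, speaker_opt=g.speaker_opt, label=label))
    return GameCatalog(games=tuple(labelled))


def default_catalog() -> GameCatalog:
    """The twelve-game catalog on the default grids."""
    return enumerate_games(DEFAULT_SPACE)
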