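"""The generational engine: selection, parental learning, mutation.

Each generation, every agent's payoff against the (other) population is
computed via the trace formulas, converted to fitness f = exp(eta * Pi),
and a full offspring generation is produced by one multinomial draw of N
parents per role with probabilities proportional to fitness (classic
Wright-Fisher sampling; equal fitnesses reduce to neutral drift without a
special case).  With probability 1 - mu an offspring learns each row of
its parent's matrix from k categorical samples; with probability mu the
matrix is replaced by a fresh uniform draw from the space of
row-stochastic matrices.  In symmetric mode each agent carries a (P, Q)
pair and the two matrices mutate independently; in asymmetric mode there
are separate speaker and listener populations of size N, each agent
holding a single matrix.

Randomness is consumed in a fixed, documented order per generation
(parent draws per role, then learning, then mutation masks, then mutant
matrices), so a realization is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics
from .game_space import DEFAULT_SPACE, MisalignmentGame, ValidationError
from .payoff_engine import fitness as _fitness
from .payoff_engine import population_payoffs
from .strategy import initial_matrices

__all__ = [
    "SimConfig",
    "PopulationState",
    "TrajectoryLog",
    "EnsembleSummary",
    "step",
    "run_realization",
    "run_ensemble",
]

TRAJECTORY_COLUMNS = [
    "generation", "breadth1", "breadth2", "breadth3",
    "swap_speaker", "swap_listener",
    "meaning_loss_S", "meaning_loss_L",
    "mean_fitness_speaker", "mean_fitness_listener",
]


@dataclass
class SimConfig:
    """All parameters of one simulation run.

    Defaults follow the study conditions: selection strength eta = 10
    acting on O(1) per-opponent payoffs, population size 100 per role in
    asymmetric play (200 in symmetric play), learning parameter k = 100,
    mutation probability mu = 0.001 per matrix, and 5000 generations.
    ``record_every`` defaults to 1 for runs of at most 1000 generations
    and 10 otherwise (log-size control only; metric definitions are
    unaffected, though per-generation swap rates require record_every=1).
    """

    game: MisalignmentGame
    mode: str = "asymmetric"
    N: Optional[int] = None
    eta: float = 10.0
    mu: float = 0.001
    k: int = 100
    generations: int = 5000
    realizations: int = 1
    seed: int = 0
    record_every: Optional[int] = None
    payoff_aggregation: str = "mean"
    innovation: Optional[object] = None  # an InnovationSchedule, or None
    mutation_new_word: str = "simplex"

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValidationError(f"mode must be symmetric or asymmetric, got {self.mode!r}")
        if self.N is None:
            self.N = 100 if self.mode == "asymmetric" else 200
        if self.N < 2:
            raise ValidationError("population size N must be >= 2")
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError("mutation probability mu must lie in [0, 1]")
        if self.k < 1:
            raise ValidationError("learning parameter k must be >= 1")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if self.realizations < 1:
            raise ValidationError("realizations must be >= 1")
        if self.eta <= 0:
            raise ValidationError("selection strength eta must be > 0")
        if self.payoff_aggregation not in ("mean", "sum"):
            raise ValidationError("payoff_aggregation must be 'mean' or 'sum'")
        if self.record_every is None:
            self.record_every = 1 if self.generations <= 1000 else 10
        if self.record_every < 1:
            raise ValidationError("record_every must be >= 1")
        if self.mutation_new_word not in ("simplex", "forced"):
            raise ValidationError("mutation_new_word must be 'simplex' or 'forced'")


@dataclass
class PopulationState:
    """Strategy stacks of one generation.

    ``P`` has shape (N, I, J) and ``Q`` shape (N, J, K).  In asymmetric
    mode these are the speaker and listener populations; in symmetric
    mode agent ``n`` holds the pair ``(P[n], Q[n])``.
    """

    mode: str
    P: np.ndarray
    Q: np.ndarray
    generation: int = 0

    @classmethod
    def initial(cls, mode: str, N: int, space=DEFAULT_SPACE) -> "PopulationState":
        """All agents start with the perfectly informative language."""
        P0, Q0 = initial_matrices(space)
        return cls(
            mode=mode,
            P=np.broadcast_to(P0, (N,) + P0.shape).copy(),
            Q=np.broadcast_to(Q0, (N,) + Q0.shape).copy(),
            generation=0,
        )

    @property
    def size(self) -> int:
        return self.P.shape[0]

    @property
    def n_words(self) -> int:
        return self.P.shape[2]


def _select_parents(fit: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """One multinomial Wright-Fisher draw of N parent indices, ~ fitness."""
    total = fit.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FloatingPointError(
            "all fitnesses underflowed to zero; eta is too large for the payoff scale"
        )
    counts = rng.multinomial(N, fit / total)
    return np.repeat(np.arange(fit.size), counts)


def _learn_stack(parents: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-sample parental learning applied to every row of a (N, R, C) stack."""
    N, R, C = parents.shape
    counts = rng.multinomial(k, parents.reshape(N * R, C))
    return counts.reshape(N, R, C) / float(k)


def _mutate_stack(stack: np.ndarray, mu: float, rng: np.random.Generator,
                  force_new_word: bool = False) -> np.ndarray:
    """Replace each agent's matrix with prob. mu by fresh uniform-simplex rows.

    With ``force_new_word`` (an alternative reading of how innovated words
    enter speech), each mutant speaker additionally devotes one uniformly
    chosen state entirely to the newest word.
    """
    N, R, C = stack.shape
    mask = rng.random(N) < mu
    n_mut = int(mask.sum())
    if n_mut:
        if C == 1:
            stack[mask] = 1.0
        else:
            fresh = rng.dirichlet(np.ones(C), size=(n_mut, R))
            if force_new_word:
                rows = rng.integers(R, size=n_mut)
                fresh[np.arange(n_mut), rows] = 0.0
                fresh[np.arange(n_mut), rows, C - 1] = 1.0
            stack[mask] = fresh
    return stack


def _reproduce(pop: PopulationState, fit_P: np.ndarray, fit_Q: np.ndarray,
               config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Produce the next generation given precomputed fitnesses.

    ``fit_P``/``fit_Q`` are the fitnesses governing reproduction of the P
    and Q stacks: per-role fitnesses in asymmetric mode, the same shared
    array in symmetric mode.
    """
    N = pop.size
    if pop.mode == "asymmetric":
        parents_P = _select_parents(fit_P, N, rng)
        parents_Q = _select_parents(fit_Q, N, rng)
    else:
        parents_P = _select_parents(fit_P, N, rng)
        parents_Q = parents_P
    force = config.innovation is not None and config.mutation_new_word == "forced"
    newP = _learn_stack(pop.P[parents_P], config.k, rng)
    newP = _mutate_stack(newP, config.mu, rng, force_new_word=force)
    newQ = _learn_stack(pop.Q[parents_Q], config.k, rng)
    newQ = _mutate_stack(newQ, config.mu, rng)
    return PopulationState(mode=pop.mode, P=newP, Q=newQ, generation=pop.generation + 1)


def step(population: PopulationState, config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Advance the population by one full generation.

    Computes payoffs and fitnesses, samples parents proportionally to
    fitness, and applies parental learning and mutation.  Mutation
    overwrites the learned matrix for the affected agent.
    """
    payoffs = population_payoffs(population, config.game, config.payoff_aggregation)
    if population.mode == "asymmetric":
        fit_P = _fitness(payoffs[0], config.eta)
        fit_Q = _fitness(payoffs[1], config.eta)
    else:
        fit_P = fit_Q = _fitness(payoffs, config.eta)
    return _reproduce(population, fit_P, fit_Q, config, rng)


@dataclass
class TrajectoryLog:
    """Per-generation summaries of one realization."""

    frame: pd.DataFrame
    record_every: int
    seed: int
    game_label: Optional[str]
    params: dict
    final_speaker_mean: np.ndarray
    final_listener_mean: np.ndarray


def _pad_to(mat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mat.shape == shape:
        return mat
    out = np.zeros(shape)
    out[: mat.shape[0], : mat.shape[1]] = mat
    return out


def _class_stats(breadths: np.ndarray, fit: np.ndarray, n_max: int) -> dict:
    """Frequency and mean fitness of each verbosity class 1..n_max."""
    out = {}
    for n in range(1, n_max + 1):
        sel = breadths == n
        out[f"class_freq_{n}"] = float(sel.mean())
        out[f"class_fitness_{n}"] = float(fit[sel].mean()) if sel.any() else float("nan")
    return out


def run_realization(config: SimConfig) -> TrajectoryLog:
    """Run one realization: initial informative language, then `generations` steps.

    Deterministic given ``config.seed``.  Records, every ``record_every``
    generations (always including generation 0), the breadth fractions of
    the original three-word lexicon, speaker/listener swap events against
    the previous generation, the global meaning-loss metrics, and mean
    fitness per role.  When an innovation schedule is configured, the
    lexicon is expanded on schedule and per-verbosity-class frequencies
    and fitnesses are logged as well.
    """
    space = config.game.space
    rng = np.random.default_rng(config.seed)
    pop = PopulationState.initial(config.mode, config.N, space)
    sched = config.innovation

    n_expansions = 0
    if sched is not None:
        n_expansions = max(0, (config.generations - 1) // sched.period)
        if sched.max_words is not None:
            n_expansions = min(n_expansions, sched.max_words - pop.n_words)
    max_words = pop.n_words + n_expansions
    original_J = min(3, pop.n_words)
    track_loss = space.n_states == 3 and space.n_actions == 5

    prev_S = prev_L = None
    records = []
    for g in range(config.generations + 1):
        payoffs = population_payoffs(pop, config.game, config.payoff_aggregation)
        if config.mode == "asymmetric":
            fit_P = _fitness(payoffs[0], config.eta)
            fit_Q = _fitness(payoffs[1], config.eta)
        else:
            fit_P = fit_Q = _fitness(payoffs, config.eta)

        S_bar, L_bar = metrics.population_average(pop.P, pop.Q)
        if prev_S is None:
            swap_s = swap_l = 0
        else:
            shape_S = (S_bar.shape[0], max(S_bar.shape[1], prev_S.shape[1]))
            shape_L = (max(L_bar.shape[0], prev_L.shape[0]), L_bar.shape[1])
            swap_s = metrics.speaker_swap_events(_pad_to(prev_S, shape_S), _pad_to(S_bar, shape_S))
            swap_l = metrics.listener_swap_events(_pad_to(prev_L, shape_L), _pad_to(L_bar, shape_L))
        prev_S, prev_L = S_bar, L_bar

        if g % config.record_every == 0 or g == config.generations:
            fracs = metrics.breadth_fractions(pop.P[:, :, :original_J], n_words=original_J)
            row = {
                "generation": g,
                "breadth1": fracs[0] if original_J >= 1 else np.nan,
                "breadth2": fracs[1] if original_J >= 2 else np.nan,
                "breadth3": fracs[2] if original_J >= 3 else np.nan,
                "swap_speaker": swap_s,
                "swap_listener": swap_l,
                "meaning_loss_S": metrics.meaning_loss_speaker(S_bar[:3, :3]) if track_loss else np.nan,
                "meaning_loss_L": metrics.meaning_loss_listener(L_bar[:3, :5]) if track_loss else np.nan,
                "mean_fitness_speaker": float(fit_P.mean()),
                "mean_fitness_listener": float(fit_Q.mean()),
            }
            if sched is not None:
                breadths = np.count_nonzero(pop.P.sum(axis=1) > 0, axis=1)
                row["n_words"] = pop.n_words
                row.update(_class_stats(breadths, fit_P, max_words))
            records.append(row)

        if g == config.generations:
            break

        if (
            sched is not None
            and g > 0
            and g % sched.period == 0
            and (sched.max_words is None or pop.n_words < sched.max_words)
        ):
            from .innovation import expand_lexicon  # deferred to avoid an import cycle

            # Expansion adds a zero speaker column and an unreachable
            # listener row, so the fitnesses just computed remain exact.
            pop = expand_lexicon(pop)
            prev_S = _pad_to(prev_S, (prev_S.shape[0], pop.n_words))
            prev_L = np.vstack([prev_L, np.zeros((1, prev_L.shape[1]))])
            prev_L[-1, -1] = 1.0

        pop = _reproduce(pop, fit_P, fit_Q, config, rng)

    frame = pd.DataFrame.from_records(records)
    return TrajectoryLog(
        frame=frame,
        record_every=config.record_every,
        seed=config.seed,
        game_label=config.game.label,
        params={
            "mode": config.mode, "N": config.N, "eta": config.eta, "mu": config.mu,
            "k": config.k, "generations": config.generations,
            "payoff_aggregation": config.payoff_aggregation,
        },
        final_speaker_mean=prev_S,
        final_listener_mean=prev_L,
    )


@dataclass
class EnsembleSummary:
    """Per-generation means and standard deviations across realizations."""

    mean: pd.DataFrame
    std: pd.DataFrame
    n_realizations: int
    trajectories: Optional[list] = None

    def final_mean(self) -> pd.Series:
        return self.mean.iloc[-1]


def run_ensemble(config: SimConfig, n_realizations: Optional[int] = None,
                 keep_trajectories: bool = False) -> EnsembleSummary:
    """Run independent realizations and summarize the logged metrics.

    Realization r uses seed ``config.seed + r``, so ensembles are
    reproducible and can be sharded across processes by seed range.
    """
    n = n_realizations if n_realizations is not None else config.realizations
    if n < 1:
        raise ValidationError("need at least one realization")
    logs = []
    for r in range(n):
        logs.append(run_realization(replace(config, seed=config.seed + r)))
    frames = pd.concat([log.frame for log in logs], keys=range(n))
    grouped = frames.groupby("generation", sort=True)
    mean = grouped.mean().reset_index()
    std = grouped.std(ddof=0).reset_index()
    return EnsembleSummary(
        mean=mean, std=std, n_realizations=n,
        trajectories=logs if keep_trajectories else None,
    )
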