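"""Marine Predator Algorithm with a random spiral flight strategy (RSFS-MPA).

A wrapper feature selector: candidate solutions are real vectors in
[lower, upper]^d, binarized by a threshold transfer rule into feature
masks, and scored by a fitness combining a surrogate classifier's
cross-validated error with a sparsity penalty (lower is better).

The MPA alternates three phases over the iteration budget, mimicking the
predator/prey velocity ratio:

* phase 1 (first third): Brownian steps around the elite — exploration;
  the RSFS spiral update is additionally applied here with a per-prey
  probability, widening the search with a randomized spiral factor;
* phase 2 (middle third): the population splits — first half takes Levy
  steps (exploration), second half Brownian steps contracted toward the
  elite by the adaptive parameter A — transition;
* phase 3 (last third): Levy steps around the elite scaled by A —
  exploitation.

A fish-aggregation-device (FADs) perturbation injects occasional long
jumps to escape local optima. The elite matrix replicates the best
position found so far, so best fitness is monotone non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import gamma as _gamma
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .config import MPAConfig, spawn_seed
from .dataset import TabularDataset
from .reports import register_report

__all__ = [
    "Population",
    "FeatureMask",
    "FSResult",
    "initialize",
    "binarize",
    "phase_of",
    "adaptive_A",
    "levy_vector",
    "step_phase1",
    "step_phase2",
    "step_phase3",
    "fads_jump",
    "rsfs_update",
    "SurrogateFitness",
    "select_features",
]

log = logging.getLogger(__name__)

FitnessFn = Callable[[np.ndarray], float]


@register_report
@dataclass
class FeatureMask:
    """Boolean feature subset; at least one feature is always selected."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 1 or not self.selected.any():
            raise ValueError("mask must be 1-D and select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def names(self, dataset: TabularDataset) -> tuple[str, ...]:
        return tuple(dataset.feature_names[j] for j in self.indices())


@dataclass
class Population:
    """Prey positions with fitness, plus the best-so-far (elite) solution."""

    prey: np.ndarray            # (n_pop, d), within bounds
    fitness: np.ndarray         # (n_pop,), lower is better
    best_position: np.ndarray   # (d,)
    best_fitness: float

    @property
    def elite(self) -> np.ndarray:
        """Best position replicated to the population shape."""
        return np.broadcast_to(self.best_position, self.prey.shape)

    @property
    def n_pop(self) -> int:
        return self.prey.shape[0]

    @property
    def d(self) -> int:
        return self.prey.shape[1]


@register_report
@dataclass
class FSResult:
    mask: FeatureMask
    best_fitness: float
    history: list = field(default_factory=list)  # best fitness per iteration
    n_evaluations: int = 0
    seed: int = 0
    selected_names: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# schedule analytics and elementary moves
# --------------------------------------------------------------------------
def phase_of(iteration: int, max_iter: int) -> int:
    """Thirds rule: phase 1, 2 or 3 by position in the iteration budget."""
    if not 0 <= iteration < max_iter:
        raise ValueError("iteration out of range")
    if iteration < max_iter / 3:
        return 1
    if iteration < 2 * max_iter / 3:
        return 2
    return 3


def adaptive_A(iteration: int, max_iter: int) -> float:
    """Control parameter A = (1 - t/T)^(2 t/T): 1 at start, 0 at the end."""
    frac = iteration / max_iter
    return float((1.0 - frac) ** (2.0 * frac))


def levy_vector(d: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step vector via the Mantegna algorithm."""
    if not 1.0 < exponent <= 2.0:
        raise ValueError("levy exponent must lie in (1, 2]")
    a = exponent
    sigma = (
        _gamma(1 + a) * math.sin(math.pi * a / 2)
        / (_gamma((1 + a) / 2) * a * 2 ** ((a - 1) / 2))
    ) ** (1 / a)
    u = rng.normal(0.0, sigma, size=d)
    v = rng.normal(0.0, 1.0, size=d)
    return u / np.abs(v) ** (1 / a)


def _levy_matrix(shape: tuple[int, int], exponent: float, rng: np.random.Generator) -> np.ndarray:
    return np.stack([levy_vector(shape[1], exponent, rng) for _ in range(shape[0])])


def binarize(position: np.ndarray, threshold: float = 0.5) -> FeatureMask:
    """Transfer rule: feature j selected iff position[j] > threshold.

    An empty result is rescued by forcing the single largest coordinate on.
    """
    position = np.asarray(position, dtype=float)
    if not np.isfinite(position).all():
        raise ValueError("position must be finite")
    selected = position > threshold
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(position))] = True
    return FeatureMask(selected)


def _clamp(prey: np.ndarray, config: MPAConfig) -> np.ndarray:
    return np.clip(prey, config.lower, config.upper)


# --------------------------------------------------------------------------
# phase operators
# --------------------------------------------------------------------------
def step_phase1(pop: Population, config: MPAConfig, rng: np.random.Generator) -> Population:
    """Exploration: Brownian step around the elite for every prey."""
    shape = pop.prey.shape
    R_B = rng.standard_normal(shape)
    N = rng.random(shape)
    step = R_B * (pop.elite - R_B * pop.prey)
    pop.prey = _clamp(pop.prey + config.step_coeff * N * step, config)
    return pop


def step_phase2(
    pop: Population, config: MPAConfig, iteration: int, rng: np.random.Generator
) -> Population:
    """Transition: first half Levy exploration, second half Brownian exploitation."""
    n, d = pop.prey.shape
    first = np.arange(n) < n / 2
    A = adaptive_A(iteration, config.max_iter)
    # exploring half
    idx1 = np.flatnonzero(first)
    R_L = _levy_matrix((idx1.size, d), config.levy_exponent, rng)
    N = rng.random((idx1.size, d))
    elite1 = pop.elite[idx1]
    step = R_L * (elite1 - R_L * pop.prey[idx1])
    pop.prey[idx1] = pop.prey[idx1] + config.step_coeff * N * step
    # exploiting half
    idx2 = np.flatnonzero(~first)
    R_B = rng.standard_normal((idx2.size, d))
    elite2 = pop.elite[idx2]
    step = R_B * (R_B * elite2 - pop.prey[idx2])
    pop.prey[idx2] = elite2 + config.step_coeff * A * step
    pop.prey = _clamp(pop.prey, config)
    return pop


def step_phase3(
    pop: Population, config: MPAConfig, iteration: int, rng: np.random.Generator
) -> Population:
    """Exploitation: Levy step around the elite, contracted by A."""
    A = adaptive_A(iteration, config.max_iter)
    R_L = _levy_matrix(pop.prey.shape, config.levy_exponent, rng)
    step = R_L * (R_L * pop.elite - pop.prey)
    pop.prey = _clamp(pop.elite + config.step_coeff * A * step, config)
    return pop


def fads_jump(
    pop: Population, config: MPAConfig, iteration: int, rng: np.random.Generator
) -> Population:
    """Fish-aggregation-device perturbation: occasional long jumps."""
    n, d = pop.prey.shape
    r = rng.random()
    if r <= config.fads:
        CF = adaptive_A(iteration, config.max_iter)
        U = (rng.random((n, d)) < config.fads).astype(float)
        R = rng.random((n, d))
        jump = CF * (config.lower + R * (config.upper - config.lower)) * U
        pop.prey = pop.prey + jump
    else:
        r1 = rng.integers(0, n, size=n)
        r2 = rng.integers(0, n, size=n)
        scale = config.fads * (1.0 - r) + r
        pop.prey = pop.prey + scale * (pop.prey[r1] - pop.prey[r2])
    pop.prey = _clamp(pop.prey, config)
    return pop


def rsfs_update(
    pop: Population, config: MPAConfig, iteration: int, rng: np.random.Generator
) -> Population:
    """Random spiral flight around the elite, applied per prey with
    probability ``rsfs_prob`` (exploration-phase enhancement).

    Spiral factor z = exp(k cos(pi (1 - t/T))) with k drawn uniformly from
    [k_min, k_max]; the prey moves by exp(zL) cos(2 pi L) |Elite - Prey|
    with L uniform in [-1, 1].
    """
    n = pop.n_pop
    for i in range(n):
        if rng.random() >= config.rsfs_prob:
            continue
        k = rng.uniform(config.k_min, config.k_max)
        L = rng.uniform(-1.0, 1.0)
        z = math.exp(k * math.cos(math.pi * (1.0 - iteration / config.max_iter)))
        move = math.exp(z * L) * math.cos(2.0 * math.pi * L)
        pop.prey[i] = pop.prey[i] + move * np.abs(pop.best_position - pop.prey[i])
    pop.prey = _clamp(pop.prey, config)
    return pop


# --------------------------------------------------------------------------
# fitness
# --------------------------------------------------------------------------
class SurrogateFitness:
    """Default wrapper objective: alpha * CV-error of a fast logistic
    surrogate on the masked features + beta * selected fraction.

    Folds and surrogate seed are fixed at construction, so within a run the
    fitness is a deterministic function of the mask; results are cached by
    mask so repeated binarizations cost nothing.
    """

    def __init__(self, dataset: TabularDataset, config: MPAConfig, seed: int) -> None:
        self.X = dataset.features
        self.y = dataset.labels
        self.config = config
        self.seed = seed
        self.n_evaluations = 0
        self._cache: dict[tuple, float] = {}
        counts = np.bincount(self.y)
        self._folds = min(config.surrogate_folds, int(counts.min()))
        if self._folds < 2:
            raise ValueError("each class needs >= 2 members for surrogate CV")

    def __call__(self, selected: np.ndarray) -> float:
        key = tuple(np.flatnonzero(selected))
        if key in self._cache:
            return self._cache[key]
        cv = StratifiedKFold(n_splits=self._folds, shuffle=True, random_state=self.seed)
        Xs = self.X[:, selected]
        errors = []
        for train_idx, test_idx in cv.split(Xs, self.y):
            clf = LogisticRegression(max_iter=500)
            clf.fit(Xs[train_idx], self.y[train_idx])
            errors.append(1.0 - clf.score(Xs[test_idx], self.y[test_idx]))
        sparsity = float(selected.sum()) / selected.size
        value = self.config.fitness_alpha * float(np.mean(errors)) + (
            self.config.fitness_beta * sparsity
        )
        self._cache[key] = value
        self.n_evaluations += 1
        return value


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------
def initialize(config: MPAConfig, d: int, rng: np.random.Generator, fitness: FitnessFn) -> Population:
    """Uniform prey in [lower, upper]^d; elite from the best initial row."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    prey = config.lower + rng.random((config.n_pop, d)) * (config.upper - config.lower)
    fit = _evaluate_rows(prey, config, fitness)
    best = int(np.argmin(fit))
    return Population(
        prey=prey,
        fitness=fit,
        best_position=prey[best].copy(),
        best_fitness=float(fit[best]),
    )


def _evaluate_rows(prey: np.ndarray, config: MPAConfig, fitness: FitnessFn) -> np.ndarray:
    out = np.empty(prey.shape[0])
    for i, row in enumerate(prey):
        mask = binarize(row, config.transfer_threshold)
        out[i] = fitness(mask.selected)
    return out


def _update_elite(pop: Population, config: MPAConfig, fitness: FitnessFn) -> None:
    pop.fitness = _evaluate_rows(pop.prey, config, fitness)
    best = int(np.argmin(pop.fitness))
    if pop.fitness[best] < pop.best_fitness:
        pop.best_fitness = float(pop.fitness[best])
        pop.best_position = pop.prey[best].copy()


def select_features(
    dataset: TabularDataset,
    config: MPAConfig | None = None,
    seed: int = 0,
    fitness: FitnessFn | None = None,
) -> FSResult:
    """Run the full RSFS-MPA search and return the best feature mask.

    Fully reproducible from (dataset, config, seed). ``fitness`` is
    pluggable; the default is the logistic-surrogate objective.
    """
    config = config or MPAConfig()
    config.validate()
    d = dataset.n_features
    if d < 2:
        raise ValueError("feature selection needs at least 2 features")
    rng = np.random.default_rng(seed)
    if fitness is None:
        fitness = SurrogateFitness(dataset, config, spawn_seed(seed, "surrogate"))

    pop = initialize(config, d, rng, fitness)
    history: list[float] = []
    for it in range(config.max_iter):
        phase = phase_of(it, config.max_iter)
        try:
            if phase == 1:
                step_phase1(pop, config, rng)
                rsfs_update(pop, config, it, rng)
            elif phase == 2:
                step_phase2(pop, config, it, rng)
            else:
                step_phase3(pop, config, it, rng)
            _update_elite(pop, config, fitness)
            fads_jump(pop, config, it, rng)
            _update_elite(pop, config, fitness)
        except Exception as exc:  # annotate with iteration context
            raise RuntimeError(f"fitness evaluation failed at iteration {it}") from exc
        history.append(pop.best_fitness)

    mask = binarize(pop.best_position, config.transfer_threshold)
    n_evals = getattr(fitness, "n_evaluations", 0)
    return FSResult(
        mask=mask,
        best_fitness=pop.best_fitness,
        history=history,
        n_evaluations=int(n_evals),
        seed=seed,
        selected_names=mask.names(dataset),
    )
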