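"""Sparrow search algorithm (SSA) with optional Logistic-chaos initialization.

SSA is a population metaheuristic that mimics the foraging division of labour
in sparrow flocks.  Each iteration the population is ranked by fitness and
split into three overlapping roles:

* **finders** (producers): the best ``finder_fraction`` of the flock.  With a
  per-iteration alarm draw ``R < ST`` (safe environment) finder ``i`` shrinks
  its position multiplicatively, ``X <- X * exp(-i / (alpha * T))`` with
  ``alpha ~ U(0, 1]``; under alarm (``R >= ST``) it takes a Gaussian step
  ``X <- X + Q``.
* **joiners** (scroungers): the remaining birds, indexed by fitness rank
  ``i``.  The hungrier half (``i > n/2``) relocates with
  ``X <- Q * exp((X_worst - X) / i^2)``; the rest forage around the best
  finder's position ``X_P`` along a random +-1 direction,
  ``X <- X_P + mean_j(a_j * |X_j - X_Pj|)`` with ``a ~ Rademacher^d`` (this is
  the rank-1 pseudo-inverse step ``|X - X_P| . A+ . L`` with ``A+ = A^T / d``).
* **scouts** (early warners): a fresh random 10-20% sample.  Birds worse than
  the global best jump toward it, ``X <- X_B + beta * |X - X_B|`` with
  ``beta ~ N(0, 1)``; the best bird itself diffuses away from the worst with a
  denominator guard ``(f_i - f_w) + eps``.

All moves are clipped to the box constraints and the reported best is an
elitist archive (never worsens).  The **LCSSA** variant replaces the uniform
initial population with per-dimension orbits of the Logistic map
``y_{k+1} = a * y_k * (1 - y_k)`` (fully chaotic at ``a = 4``), whose orbit
fills (0, 1) with the arcsine-shaped invariant density and thus gives a
reproducible, well-spread initial flock.

Randomness: every stochastic quantity is drawn from a single
``numpy.random.Generator`` in a fixed, documented order (alarm value, then
finder draws in rank order, then joiner draws in rank order, then scout
draws in selection order), so seeded runs are exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SsaConfig",
    "Population",
    "OptimizeResult",
    "logistic_sequence",
    "init_positions",
    "init_population",
    "update_finders",
    "update_joiners",
    "update_scouts",
    "optimize",
]

#: Logistic-map seeds on short periodic orbits (0.5 -> 1 -> 0, 0.75 fixed
#: point, 0.25 -> 0.75); initial conditions are resampled away from these.
_DEGENERATE_SEEDS = (0.25, 0.5, 0.75)


@dataclass
class SsaConfig:
    """Hyperparameters and box constraints of one optimizer run.

    ``safety_value`` (ST) lies in [0.5, 1]; ``scout_fraction`` defaults to the
    top of the conventional 10-20% band (0 is allowed to express the
    degenerate no-scout random walk); ``finder_fraction`` defaults to 0.2.
    ``exp_form`` selects the finder contraction exponent: "canonical" is
    ``exp(-i/(alpha*T))``; "printed" is the literal ``exp(-i*alpha*T)``
    rendering, kept only for auditing (it underflows for realistic i*T).
    """

    dims: int
    lower_bounds: np.ndarray | float = -1.0
    upper_bounds: np.ndarray | float = 1.0
    pop_size: int = 20
    max_iters: int = 20
    safety_value: float = 0.8
    finder_fraction: float = 0.2
    scout_fraction: float = 0.2
    logistic_a: float = 4.0
    init_mode: str = "uniform"
    exp_form: str = "canonical"
    denom_guard: float = 1e-50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError(f"dims must be >= 1, got {self.dims}")
        if self.pop_size < 4:
            raise ValueError(f"pop_size must be >= 4, got {self.pop_size}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")
        if not 0.5 <= self.safety_value <= 1.0:
            raise ValueError(f"safety_value must lie in [0.5, 1], got {self.safety_value}")
        if not 0.0 < self.finder_fraction <= 1.0:
            raise ValueError(f"finder_fraction must lie in (0, 1], got {self.finder_fraction}")
        if not 0.0 <= self.scout_fraction <= 0.2:
            raise ValueError(f"scout_fraction must lie in [0, 0.2], got {self.scout_fraction}")
        if not 0.0 <= self.logistic_a <= 4.0:
            raise ValueError(f"logistic_a must lie in [0, 4], got {self.logistic_a}")
        if self.init_mode not in ("uniform", "logistic"):
            raise ValueError(f"init_mode must be 'uniform' or 'logistic', got {self.init_mode!r}")
        if self.exp_form not in ("canonical", "printed"):
            raise ValueError(f"exp_form must be 'canonical' or 'printed', got {self.exp_form!r}")
        self.lower_bounds = np.broadcast_to(
            np.asarray(self.lower_bounds, dtype=float), (self.dims,)
        ).copy()
        self.upper_bounds = np.broadcast_to(
            np.asarray(self.upper_bounds, dtype=float), (self.dims,)
        ).copy()
        if not np.all(self.lower_bounds < self.upper_bounds):
            raise ValueError("lower_bounds must be elementwise < upper_bounds")

    @property
    def n_finders(self) -> int:
        return max(1, int(round(self.finder_fraction * self.pop_size)))

    @property
    def n_scouts(self) -> int:
        return int(round(self.scout_fraction * self.pop_size))


@dataclass
class Population:
    """Positions and fitnesses of the flock; best/worst derive from fitness.

    Ties in fitness are broken by the lower row index (stable ordering).
    """

    positions: np.ndarray
    fitness: np.ndarray

    def rank_order(self) -> np.ndarray:
        """Row indices sorted best (lowest fitness) to worst, stable."""
        return np.argsort(self.fitness, kind="stable")

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def worst_index(self) -> int:
        return int(np.argmax(self.fitness))

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[self.best_index]

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])

    @property
    def worst_position(self) -> np.ndarray:
        return self.positions[self.worst_index]

    @property
    def worst_fitness(self) -> float:
        return float(self.fitness[self.worst_index])


@dataclass
class OptimizeResult:
    """Outcome of one optimizer run; ``history`` is the elitist best trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray = field(repr=False)
    evaluations: int = 0


def logistic_sequence(y0: float, a: float = 4.0, length: int = 1) -> np.ndarray:
    """Orbit of the Logistic map ``y_{k+1} = a * y_k * (1 - y_k)``.

    Returns ``length`` values starting with ``y0`` itself.  Requires
    ``0 < y0 < 1`` and ``0 <= a <= 4`` so the orbit stays in [0, 1].
    """
    if not 0.0 < y0 < 1.0:
        raise ValueError(f"y0 must lie in (0, 1), got {y0}")
    if not 0.0 <= a <= 4.0:
        raise ValueError(f"a must lie in [0, 4], got {a}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    seq = np.empty(length)
    y = float(y0)
    for k in range(length):
        seq[k] = y
        y = a * y * (1.0 - y)
    return seq


def _draw_logistic_seed(rng: np.random.Generator) -> float:
    """Initial condition in (0.01, 0.99), away from short periodic orbits."""
    while True:
        y0 = rng.uniform(0.01, 0.99)
        if min(abs(y0 - p) for p in _DEGENERATE_SEEDS) > 1e-6:
            return y0


def init_positions(cfg: SsaConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial position matrix (pop_size x dims) inside the bounds.

    "uniform": i.i.d. uniform.  "logistic": each dimension is one chaotic
    orbit of length pop_size (fresh random initial condition per dimension),
    affinely mapped from [0, 1] onto [lower, upper].
    """
    n, d = cfg.pop_size, cfg.dims
    span = cfg.upper_bounds - cfg.lower_bounds
    if cfg.init_mode == "uniform":
        return cfg.lower_bounds + rng.random((n, d)) * span
    cols = np.empty((n, d))
    for j in range(d):
        y0 = _draw_logistic_seed(rng)
        cols[:, j] = logistic_sequence(y0, cfg.logistic_a, n)
    return cfg.lower_bounds + cols * span


def _evaluate_rows(objective, positions: np.ndarray) -> np.ndarray:
    """Row-wise objective values; non-finite results become +inf with a warning."""
    vals = np.empty(positions.shape[0])
    for i, row in enumerate(positions):
        v = float(objective(row))
        if not np.isfinite(v):
            warnings.warn(
                f"objective returned non-finite value {v!r}; treating as +inf",
                stacklevel=2,
            )
            v = np.inf
        vals[i] = v
    return vals


def init_population(
    cfg: SsaConfig, objective=None, rng: np.random.Generator | None = None
) -> Population:
    """Draw an initial flock; fitness is evaluated if an objective is given."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    positions = init_positions(cfg, rng)
    if objective is None:
        fitness = np.full(cfg.pop_size, np.nan)
    else:
        fitness = _evaluate_rows(objective, positions)
    return Population(positions=positions, fitness=fitness)


def _clip(x: np.ndarray, cfg: SsaConfig) -> np.ndarray:
    return np.clip(x, cfg.lower_bounds, cfg.upper_bounds)


def update_finders(
    pop: Population, t: int, cfg: SsaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Finder (producer) phase; returns the updated row indices.

    Draw order: alarm value R, then (safe branch) one alpha per finder in
    rank order, or (alarm branch) the full Gaussian step matrix.  ``t`` is
    the current iteration, kept for interface completeness (the canonical
    contraction depends only on rank, alpha and max_iters).
    """
    del t
    order = pop.rank_order()
    k = cfg.n_finders
    finders = order[:k]
    alarm = rng.random()
    if alarm < cfg.safety_value:
        alphas = 1.0 - rng.random(k)  # uniform on (0, 1]
        ranks = np.arange(1, k + 1, dtype=float)
        if cfg.exp_form == "canonical":
            factors = np.exp(-ranks / (alphas * cfg.max_iters))
        else:  # literal printed rendering, audit only
            factors = np.exp(-ranks * alphas * cfg.max_iters)
        pop.positions[finders] *= factors[:, None]
    else:
        q = rng.standard_normal((k, cfg.dims))
        pop.positions[finders] = pop.positions[finders] + q
    pop.positions[finders] = _clip(pop.positions[finders], cfg)
    return finders


def update_joiners(
    pop: Population, cfg: SsaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Joiner (scrounger) phase; returns the updated row indices.

    ``X_P`` is the best finder's position at entry (i.e. after the finder
    phase), ``X_L`` the globally worst position; both are snapshotted before
    any joiner moves.  Joiners are processed in fitness-rank order; the
    per-joiner draws are one Gaussian vector (far branch) or one Rademacher
    direction (producer-vicinity branch).
    """
    order = pop.rank_order()
    n, d = cfg.pop_size, cfg.dims
    k = cfg.n_finders
    x_p = pop.positions[order[0]].copy()
    x_l = pop.positions[order[-1]].copy()
    joiners = order[k:]
    for rank_idx, idx in enumerate(joiners, start=k + 1):
        x = pop.positions[idx]
        if rank_idx > 0.5 * n:
            q = rng.standard_normal(d)
            new = q * np.exp((x_l - x) / rank_idx**2)
        else:
            a = rng.integers(0, 2, size=d) * 2.0 - 1.0
            step = float(np.sum(a * np.abs(x - x_p))) / d
            new = x_p + step
        pop.positions[idx] = _clip(new, cfg)
    return joiners


def update_scouts(
    pop: Population, cfg: SsaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Scout (early-warner) phase; returns the updated row indices.

    A fresh random sample of ``scout_fraction * n`` birds (without
    replacement) is redrawn every call.  Per scout: one beta ~ N(0,1) if its
    fitness exceeds the global best, else one K ~ U[-1, 1]; the denominator
    ``(f_i - f_w) + denom_guard`` never vanishes even when the scout is the
    worst bird.
    """
    m = cfg.n_scouts
    if m == 0:
        return np.empty(0, dtype=int)
    chosen = rng.choice(cfg.pop_size, size=m, replace=False)
    x_b = pop.best_position.copy()
    x_l = pop.worst_position.copy()
    f_g = pop.best_fitness
    f_w = pop.worst_fitness
    for idx in chosen:
        x = pop.positions[idx]
        f_i = float(pop.fitness[idx])
        if f_i > f_g:
            beta = rng.standard_normal()
            new = x_b + beta * np.abs(x - x_b)
        else:
            kk = rng.uniform(-1.0, 1.0)
            new = x + kk * (np.abs(x - x_l) / ((f_i - f_w) + cfg.denom_guard))
        pop.positions[idx] = _clip(new, cfg)
    return chosen


def optimize(objective, cfg: SsaConfig) -> OptimizeResult:
    """Run the full optimizer loop and return the elitist best.

    Per iteration: finders, joiners, scouts (roles from the previous
    evaluation's fitness ranking), then one re-evaluation of the whole
    flock.  The history records the best fitness ever seen and is therefore
    non-increasing with exactly ``max_iters`` entries.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, objective, rng)
    best_f = pop.best_fitness
    best_x = pop.best_position.copy()
    history = np.empty(cfg.max_iters)
    for t in range(1, cfg.max_iters + 1):
        update_finders(pop, t, cfg, rng)
        update_joiners(pop, cfg, rng)
        update_scouts(pop, cfg, rng)
        pop.fitness = _evaluate_rows(objective, pop.positions)
        if pop.best_fitness < best_f:
            best_f = pop.best_fitness
            best_x = pop.best_position.copy()
        history[t - 1] = best_f
    return OptimizeResult(
        best_position=best_x,
        best_fitness=best_f,
        history=history,
        evaluations=cfg.pop_size * (cfg.max_iters + 1),
    )
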