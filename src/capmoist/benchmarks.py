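"""Benchmark objective functions for validating the optimizer variants.

Six classic box-constrained minimization problems: sphere (F1), Schwefel 2.22
(F2), Schwefel 1.2 / rotated hyper-ellipsoid (F3), Schwefel 2.21 / max-abs
(F4), Rosenbrock (F5) and the step function (F6).  Bounds follow the common
benchmarking convention (they are not part of the physical problem):
F1/F3/F4/F6 on [-100, 100]^d, F2 on [-10, 10]^d, F5 on [-30, 30]^d, d = 30 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["BenchmarkFunction", "BENCHMARKS", "evaluate", "compare_optimizers"]


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _schwefel_222(x: np.ndarray) -> float:
    a = np.abs(x)
    return float(np.sum(a) + np.prod(a))


def _schwefel_12(x: np.ndarray) -> float:
    c = np.cumsum(x)
    return float(np.sum(c * c))


def _max_abs(x: np.ndarray) -> float:
    return float(np.max(np.abs(x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _step(x: np.ndarray) -> float:
    return float(np.sum(np.floor(x + 0.5) ** 2))


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    func: Callable[[np.ndarray], float]
    lower: float
    upper: float
    optimum_value: float = 0.0
    #: coordinate value of the global minimizer (same in every dimension)
    optimum_coordinate: float = 0.0

    def optimum_location(self, dims: int) -> np.ndarray:
        return np.full(dims, self.optimum_coordinate)

    def __call__(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError(f"{self.name} expects a nonempty 1-D vector, got shape {x.shape}")
        return self.func(x)


BENCHMARKS: dict[str, BenchmarkFunction] = {
    "F1": BenchmarkFunction("F1", _sphere, -100.0, 100.0),
    "F2": BenchmarkFunction("F2", _schwefel_222, -10.0, 10.0),
    "F3": BenchmarkFunction("F3", _schwefel_12, -100.0, 100.0),
    "F4": BenchmarkFunction("F4", _max_abs, -100.0, 100.0),
    "F5": BenchmarkFunction("F5", _rosenbrock, -30.0, 30.0, optimum_coordinate=1.0),
    "F6": BenchmarkFunction("F6", _step, -100.0, 100.0),
}


def evaluate(name: str, x) -> float:
    """Evaluate benchmark ``name`` at point ``x``."""
    if name not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    return BENCHMARKS[name](x)


def compare_optimizers(
    function_names=("F1", "F2", "F3", "F4", "F5", "F6"),
    dims: int = 30,
    pop_size: int = 30,
    max_iters: int = 20,
    n_seeds: int = 11,
    seed0: int = 0,
) -> pd.DataFrame:
    """Paired SSA vs LCSSA comparison over several seeds.

    For each benchmark and each seed the plain sparrow search (uniform init)
    and the Logistic-chaos-initialized variant are run with identical
    hyperparameters; the final best fitness of each run is returned in a tidy
    frame with columns (function, seed, algorithm, best_fitness).
    """
    from .ssa import SsaConfig, optimize

    rows = []
    for name in function_names:
        bench = BENCHMARKS[name]
        for k in range(n_seeds):
            seed = seed0 + k
            for algorithm, init_mode in (("SSA", "uniform"), ("LCSSA", "logistic")):
                cfg = SsaConfig(
                    dims=dims,
                    lower_bounds=bench.lower,
                    upper_bounds=bench.upper,
                    pop_size=pop_size,
                    max_iters=max_iters,
                    init_mode=init_mode,
                    seed=seed,
                )
                res = optimize(bench, cfg)
                rows.append(
                    {
                        "function": name,
                        "seed": seed,
                        "algorithm": algorithm,
                        "best_fitness": res.best_fitness,
                    }
                )
    return pd.DataFrame(rows)
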