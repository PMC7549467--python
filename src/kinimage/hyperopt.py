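"""Gaussian-process Bayesian optimization of the CNN hyperparameters.

The objective is ``1 - validation AUC`` of a freshly trained CNN; the
optimizer minimizes it over a six-dimensional box (learning rate searched
log-uniformly, integer dimensions rounded).  The first ``n_initial``
points are random; afterwards a GP surrogate (Matern 5/2 plus white
noise) is fitted to all evaluations in the unit cube and the next point
maximizes expected improvement over a random candidate set.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .cnn import Hyperparameters, train_model
from .dataset import LabeledDataset
from .errors import InvalidArgumentError

_N_DIMS = 6


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds per hyperparameter; ``lr`` is sampled log-uniformly.

    The defaults form a hyper-rectangle wide enough to contain every
    optimum a practitioner would report for this architecture on data of
    this size.
    """

    lr: Tuple[float, float] = (1e-5, 1e-2)
    ep: Tuple[int, int] = (100, 300)
    f_conv1: Tuple[int, int] = (10, 100)
    f_conv2: Tuple[int, int] = (10, 100)
    d_drop1: Tuple[float, float] = (0.0, 0.25)
    out_dense1: Tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        for name in ("lr", "ep", "f_conv1", "f_conv2", "d_drop1", "out_dense1"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidArgumentError(f"{name}: require lower < upper, got ({lo}, {hi})")
        if self.lr[0] <= 0:
            raise InvalidArgumentError("lr bounds must be positive (log-uniform)")

    # -- unit-cube transform -------------------------------------------------

    def from_unit(self, u: np.ndarray) -> Hyperparameters:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        log_lo, log_hi = np.log10(self.lr[0]), np.log10(self.lr[1])

        def integer(bounds, v):
            return int(np.clip(round(bounds[0] + v * (bounds[1] - bounds[0])), *bounds))

        return Hyperparameters(
            lr=float(10 ** (log_lo + u[0] * (log_hi - log_lo))),
            ep=integer(self.ep, u[1]),
            f_conv1=integer(self.f_conv1, u[2]),
            f_conv2=integer(self.f_conv2, u[3]),
            d_drop1=float(self.d_drop1[0] + u[4] * (self.d_drop1[1] - self.d_drop1[0])),
            out_dense1=integer(self.out_dense1, u[5]),
        )

    def contains(self, h: Hyperparameters) -> bool:
        return (
            self.lr[0] <= h.lr <= self.lr[1]
            and self.ep[0] <= h.ep <= self.ep[1]
            and self.f_conv1[0] <= h.f_conv1 <= self.f_conv1[1]
            and self.f_conv2[0] <= h.f_conv2 <= self.f_conv2[1]
            and self.d_drop1[0] <= h.d_drop1 <= self.d_drop1[1]
            and self.out_dense1[0] <= h.out_dense1 <= self.out_dense1[1]
        )

    def sample(self, rng: np.random.Generator) -> Hyperparameters:
        return self.from_unit(rng.random(_N_DIMS))


DEFAULT_SPACE = SearchSpace()


@dataclass
class OptimizationResult:
    """Best point plus the full evaluation history."""

    best: Hyperparameters
    best_objective: float
    history: List[Tuple[Hyperparameters, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{**h.as_dict(), "objective": obj} for h, obj in self.history]
        return pd.DataFrame(rows)


def _expected_improvement(gp, candidates: np.ndarray, best: float, xi: float = 0.01) -> np.ndarray:
    mu, sd = gp.predict(candidates, return_std=True)
    sd = np.maximum(sd, 1e-9)
    improvement = best - mu - xi
    z = improvement / sd
    return improvement * norm.cdf(z) + sd * norm.pdf(z)


def optimize(
    objective: Callable[[Hyperparameters], float],
    space: SearchSpace = DEFAULT_SPACE,
    n_calls: int = 40,
    n_initial: int = 10,
    seed: int = 0,
    n_candidates: int = 1024,
) -> OptimizationResult:
    """Minimize ``objective`` over ``space`` with ``n_calls`` evaluations.

    The returned optimum is the argmin over every evaluated point (never
    worse than any point in the history).
    """
    if n_calls < 5:
        raise InvalidArgumentError("n_calls must be >= 5 to fit the initial design")
    n_initial = max(1, min(n_initial, n_calls))
    rng = np.random.default_rng(seed)

    X_unit: List[np.ndarray] = []
    values: List[float] = []
    history: List[Tuple[Hyperparameters, float]] = []

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(_N_DIMS), nu=2.5) + WhiteKernel(
        noise_level=1e-4
    )

    for call in range(n_calls):
        if call < n_initial:
            u = rng.random(_N_DIMS)
        else:
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=int(seed) % (2**31)
            )
            with warnings.catch_warnings():
                # kernel length-scale bounds are routinely hit on tiny designs
                warnings.simplefilter("ignore")
                gp.fit(np.array(X_unit), np.array(values))
            candidates = rng.random((n_candidates, _N_DIMS))
            ei = _expected_improvement(gp, candidates, best=min(values))
            u = candidates[int(ei.argmax())]
        h = space.from_unit(u)
        value = float(objective(h))
        X_unit.append(u)
        values.append(value)
        history.append((h, value))

    best_i = int(np.argmin(values))
    return OptimizationResult(history[best_i][0], values[best_i], history)


def make_cnn_objective(
    dataset: LabeledDataset,
    base_seed: int = 0,
    val_fraction: float = 0.2,
    group_by_participant: bool = False,
    split=None,
) -> Callable[[Hyperparameters], float]:
    """Objective factory: each call retrains the CNN from scratch with a
    call-indexed seed and returns ``1 - validation AUC``."""
    counter = {"call": 0}

    def objective(h: Hyperparameters) -> float:
        seed = int((base_seed + 7919 * counter["call"]) % (2**31))
        counter["call"] += 1
        result = train_model(
            dataset, h, seed=seed, val_fraction=val_fraction,
            group_by_participant=group_by_participant, split=split,
        )
        return 1.0 - result.auc

    return objective


def random_search(
    objective: Callable[[Hyperparameters], float],
    space: SearchSpace = DEFAULT_SPACE,
    n_calls: int = 40,
    seed: int = 0,
) -> OptimizationResult:
    """Pure random search with the same seeding scheme — the paired control
    for judging whether the GP guidance helps."""
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(n_calls):
        h = space.from_unit(rng.random(_N_DIMS))
        history.append((h, float(objective(h))))
    values = [v for _, v in history]
    best_i = int(np.argmin(values))
    return OptimizationResult(history[best_i][0], values[best_i], history)
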