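"""Fitting the feedback controller to acute-reaction duration tables.

The observable is a 36-value summary: mean second-bout duration and mean
subsequent-interbout duration for each of the 18 unique reafference
conditions of the short model-test trial.  The objective is the mean
absolute error between model and target summaries, normalized entrywise by
the target.  A derivative-free genetic algorithm searches the 8-parameter
space; the objective, not the optimizer, is the normative part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import ControllerParams, condition_summary
from .reafference import enumerate_conditions

__all__ = [
    "DurationDataset",
    "GAConfig",
    "FitResult",
    "split_dataset",
    "objective_mae",
    "fit_parameters",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
]

PARAM_NAMES = ("omega_f", "omega_r", "tau_s", "thr", "omega_s", "omega_m",
               "tau_m", "omega_i")

#: search bounds; time constants are searched on a log scale.
DEFAULT_BOUNDS = {
    "omega_f": (1e-3, 10.0),
    "omega_r": (1e-3, 10.0),
    "tau_s": (0.05, 20.0),
    "thr": (1e-3, 1.0),
    "omega_s": (1e-3, 10.0),
    "omega_m": (1e-3, 10.0),
    "tau_m": (0.05, 20.0),
    "omega_i": (1e-3, 10.0),
}

# all parameters are searched on a log10 scale: the behaviorally relevant
# weight regime spans orders of magnitude (sensor weights ~1e-2 per mm/s,
# integrator weights ~1), and a linear parametrization makes the low-weight
# regime a vanishing fraction of the search volume.
_LOG_PARAMS = PARAM_NAMES

#: contribution of a condition entry for which the model produced no output
#: (no third bout in the test trial); a finite, pessimistic stand-in for the
#: silently dropped trials of the original fitting.
MISSING_PENALTY = 2.0


@dataclass
class DurationDataset:
    """Per-condition arrays of bout and interbout durations (ms).

    ``bouts`` and ``interbouts`` map condition label -> 1-D array.  The
    canonical condition ordering is that of
    :func:`boutloop.reafference.enumerate_conditions`.
    """

    bouts: dict[str, np.ndarray]
    interbouts: dict[str, np.ndarray]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in enumerate_conditions()]

    def summary(self) -> np.ndarray:
        """36-value table of per-condition means (18 bout + 18 interbout)."""
        lb = self.labels
        b = np.array([np.mean(self.bouts[l]) for l in lb])
        i = np.array([np.mean(self.interbouts[l]) for l in lb])
        return np.concatenate([b, i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, arr in self.bouts.items():
            rows += [(label, "bout", v) for v in arr]
        for label, arr in self.interbouts.items():
            rows += [(label, "interbout", v) for v in arr]
        return pd.DataFrame(rows, columns=["condition_id", "metric", "value_ms"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DurationDataset":
        bouts, inter = {}, {}
        for (label, metric), g in df.groupby(["condition_id", "metric"]):
            (bouts if metric == "bout" else inter)[label] = g["value_ms"].to_numpy()
        return cls(bouts=bouts, interbouts=inter)


def split_dataset(ds: DurationDataset, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random per-condition 50/50 split; returns (train, test) summaries.

    Each condition array is partitioned at random (odd sizes give the extra
    element to the training half) and per-condition means of the halves
    form the two 36-value summaries.
    """
    rng = np.random.default_rng(seed)
    train_b, test_b, train_i, test_i = [], [], [], []
    for label in ds.labels:
        for store, tr, te in ((ds.bouts, train_b, test_b),
                              (ds.interbouts, train_i, test_i)):
            arr = np.asarray(store[label], dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty duration array for condition {label!r}")
            perm = rng.permutation(arr.size)
            n_train = (arr.size + 1) // 2
            tr.append(arr[perm[:n_train]].mean())
            te.append(arr[perm[n_train:]].mean() if arr.size > n_train else np.nan)
    train = np.array(train_b + train_i)
    test = np.array(test_b + test_i)
    return train, test


def objective_mae(model_summary: np.ndarray, target_summary: np.ndarray,
                  missing_penalty: float = MISSING_PENALTY) -> float:
    """Normalized mean absolute error between two 36-value summaries.

    ``mean(|model - target| / target)`` over entries; NaN model entries
    (conditions where the model produced no output) contribute
    ``missing_penalty``; NaN target entries are skipped.
    """
    m = np.asarray(model_summary, dtype=float)
    t = np.asarray(target_summary, dtype=float)
    if m.shape != t.shape:
        raise ValueError("summaries must have identical shape and ordering")
    valid_t = ~np.isnan(t)
    if (t[valid_t] == 0).any():
        raise ValueError("target summary contains zero entries; cannot normalize")
    err = np.abs(m - t) / t
    err[np.isnan(m) & valid_t] = missing_penalty
    return float(np.nanmean(err[valid_t]))


@dataclass
class GAConfig:
    population: int = 64
    generations: int = 300
    tournament_k: int = 3
    crossover_p: float = 0.5       # per-gene swap probability (uniform crossover)
    mutation_p: float = 0.3        # per-gene mutation probability
    mutation_sigma: float = 0.15   # initial Gaussian sigma, fraction of bound range
    mutation_sigma_final: float = 0.005  # sigma anneals geometrically to this
    elitism: int = 2
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    dt: float = 0.005


@dataclass
class FitResult:
    params: ControllerParams
    train_error: float
    history: np.ndarray          # best error per generation (non-increasing)
    seed: int
    test_error: float | None = None

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in PARAM_NAMES},
            "train_error": self.train_error,
            "test_error": self.test_error,
            "seed": self.seed,
            "history": self.history.tolist(),
        }


def _to_internal(x: np.ndarray, bounds) -> np.ndarray:
    """Parameter vector -> internal GA coordinates (log for time constants)."""
    y = x.copy()
    for i, name in enumerate(PARAM_NAMES):
        if name in _LOG_PARAMS:
            y[i] = np.log10(x[i])
    return y


def _from_internal(y: np.ndarray) -> np.ndarray:
    x = y.copy()
    for i, name in enumerate(PARAM_NAMES):
        if name in _LOG_PARAMS:
            x[i] = 10.0 ** y[i]
    return x


def _internal_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    lo = np.empty(8)
    hi = np.empty(8)
    for i, name in enumerate(PARAM_NAMES):
        a, b = bounds[name]
        if not (0 < a < b):
            raise ValueError(f"invalid bounds for {name}: {(a, b)}")
        if name in _LOG_PARAMS:
            a, b = np.log10(a), np.log10(b)
        lo[i], hi[i] = a, b
    return lo, hi


def fit_parameters(target_summary: np.ndarray, config: GAConfig | None = None,
                   seed: int = 0, test_summary: np.ndarray | None = None) -> FitResult:
    """Genetic-algorithm fit of the eight controller parameters.

    Tournament selection, uniform crossover, per-gene Gaussian mutation and
    elitism; deterministic given the seed.  The best-error history is
    non-increasing by construction (elitism).
    """
    cfg = GAConfig() if config is None else config
    rng = np.random.default_rng(seed)
    lo, hi = _internal_bounds(cfg.bounds)
    span = hi - lo
    target = np.asarray(target_summary, dtype=float)
    conds = enumerate_conditions()

    def evaluate(genome: np.ndarray) -> float:
        params = ControllerParams.from_array(_from_internal(genome))
        model = condition_summary(params, conds, dt=cfg.dt)
        return objective_mae(model, target)

    pop = lo + rng.random((cfg.population, 8)) * span
    fitness = np.array([evaluate(g) for g in pop])
    history = []

    for gen in range(cfg.generations):
        # mutation scale anneals geometrically: coarse exploration first,
        # fine local refinement in late generations
        frac = gen / max(cfg.generations - 1, 1)
        sigma = cfg.mutation_sigma * (cfg.mutation_sigma_final / cfg.mutation_sigma) ** frac
        order = np.argsort(fitness)
        history.append(float(fitness[order[0]]))
        elite = pop[order[: cfg.elitism]].copy()
        children = [e for e in elite]
        while len(children) < cfg.population:
            # tournament selection of two parents
            idx = rng.integers(cfg.population, size=(2, cfg.tournament_k))
            p1 = pop[idx[0][np.argmin(fitness[idx[0]])]]
            p2 = pop[idx[1][np.argmin(fitness[idx[1]])]]
            # uniform crossover
            mask = rng.random(8) < cfg.crossover_p
            child = np.where(mask, p2, p1)
            # Gaussian mutation, clipped to bounds
            mut = rng.random(8) < cfg.mutation_p
            child = child + mut * rng.normal(0.0, sigma * span)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[: cfg.population])
        fitness = np.concatenate([
            fitness[order[: cfg.elitism]],
            [evaluate(g) for g in pop[cfg.elitism:]],
        ])

    order = np.argsort(fitness)
    history.append(float(fitness[order[0]]))
    best = ControllerParams.from_array(_from_internal(pop[order[0]]))
    train_error = float(fitness[order[0]])
    test_error = None
    if test_summary is not None:
        model = condition_summary(best, conds, dt=cfg.dt)
        test_error = objective_mae(model, np.asarray(test_summary, dtype=float))
    return FitResult(params=best, train_error=train_error,
                     history=np.array(history), seed=seed, test_error=test_error)
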