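"""Ordinary-least-squares QSAR regression and descriptor subset selection.

The response throughout is pIC50; models are fitted on raw descriptor
scales (no standardisation), matching common MLR-QSAR practice for small
congeneric series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CollinearityError, SchemaError, SizeError

__all__ = [
    "DataTable",
    "SplitPlan",
    "MLRModel",
    "GAParams",
    "split",
    "fit_mlr",
    "predict",
    "select_subset",
]


@dataclass(frozen=True)
class DataTable:
    """Descriptor/response table: ids, X (n x p), y (n), descriptor names."""

    ids: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    descriptor_names: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        n, p = X.shape
        if len(self.ids) != n or len(y) != n or len(self.descriptor_names) != p:
            raise SchemaError("ids/X/y/descriptor_names dimensions disagree")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise SchemaError("table contains missing or non-finite values")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, response: str = "pIC50") -> "DataTable":
        if response not in frame.columns:
            raise SchemaError(f"response column {response!r} absent")
        names = tuple(c for c in frame.columns if c != response)
        return cls(
            ids=tuple(str(i) for i in frame.index),
            X=frame[list(names)].to_numpy(float),
            y=frame[response].to_numpy(float),
            descriptor_names=names,
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def columns(self, subset: tuple[str, ...]) -> np.ndarray:
        idx = []
        for name in subset:
            if name not in self.descriptor_names:
                raise SchemaError(f"unknown descriptor {name!r}")
            idx.append(self.descriptor_names.index(name))
        return self.X[:, idx]

    def take(self, ids) -> "DataTable":
        wanted = [self.ids.index(i) for i in ids]
        return DataTable(
            ids=tuple(self.ids[i] for i in wanted),
            X=self.X[wanted],
            y=self.y[wanted],
            descriptor_names=self.descriptor_names,
        )


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int
    strategy: str = "random"


@dataclass(frozen=True)
class MLRModel:
    intercept: float
    coefficients: dict[str, float]
    train_ids: tuple[str, ...]
    sigma: float

    @property
    def subset(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


def split(
    table: DataTable,
    fraction: float = 0.7,
    seed: int = 0,
    strategy: str = "random",
) -> SplitPlan:
    """Deterministic train/test split.

    ``random`` permutes ids with a seeded generator; ``activity_sorted``
    orders compounds by response and sends every k-th interior compound to
    the test set, keeping the response extremes in training.
    """
    if not 0 < fraction < 1:
        raise SizeError(f"fraction must be in (0, 1), got {fraction}")
    n = table.n
    n_train = int(round(n * fraction))
    n_test = n - n_train
    if n_test < 1 or n_train < 2:
        raise SizeError(f"split {fraction} leaves no usable train/test rows for n={n}")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        train = sorted(order[:n_train])
        test = sorted(order[n_train:])
    elif strategy == "activity_sorted":
        order = np.argsort(table.y, kind="stable")
        interior = list(order[1:-1])
        step = max(1, len(interior) // n_test)
        test_set = interior[::step][:n_test]
        test = sorted(test_set)
        test_lookup = set(test)
        train = [i for i in range(n) if i not in test_lookup]
    else:
        raise SchemaError(f"unknown split strategy {strategy!r}")
    return SplitPlan(
        train_ids=tuple(table.ids[i] for i in train),
        test_ids=tuple(table.ids[i] for i in test),
        fraction=fraction,
        seed=seed,
        strategy=strategy,
    )


def design_matrix(table: DataTable, subset: tuple[str, ...]) -> np.ndarray:
    """[1 | X_subset] design matrix."""
    return np.column_stack([np.ones(table.n), table.columns(tuple(subset))])


def fit_mlr(table: DataTable, subset: tuple[str, ...] | None = None) -> MLRModel:
    """OLS fit of y on the chosen descriptor subset (all columns by default).

    sigma is the residual standard error sqrt(RSS / (n - p - 1)).
    """
    subset = tuple(subset) if subset is not None else table.descriptor_names
    p = len(subset)
    if table.n < p + 2:
        raise SizeError(f"need at least {p + 2} rows to fit {p} descriptors, have {table.n}")
    A = design_matrix(table, subset)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        dependent = _dependent_columns(A, subset)
        raise CollinearityError(
            f"design matrix rank {rank} < {A.shape[1]}; dependent columns: {dependent}",
            columns=dependent,
        )
    beta, *_ = np.linalg.lstsq(A, table.y, rcond=None)
    residuals = table.y - A @ beta
    dof = table.n - p - 1
    sigma = float(np.sqrt(residuals @ residuals / dof)) if dof > 0 else float("nan")
    return MLRModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(subset, beta[1:])},
        train_ids=table.ids,
        sigma=sigma,
    )


def _dependent_columns(A: np.ndarray, subset: tuple[str, ...]) -> tuple[str, ...]:
    names = ("(intercept)",) + tuple(subset)
    dependent = []
    kept: list[int] = []
    for j in range(A.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(A[:, trial]) < len(trial):
            dependent.append(names[j])
        else:
            kept.append(j)
    return tuple(dependent)


def predict(model: MLRModel, X_query) -> np.ndarray:
    """Predicted responses ŷ = intercept + Σ coef·x for the query rows.

    Accepts a DataTable, a DataFrame with named columns, or a mapping of
    descriptor name to value(s).
    """
    names = model.subset
    if isinstance(X_query, DataTable):
        cols = X_query.columns(names)
    elif isinstance(X_query, pd.DataFrame):
        missing = [n for n in names if n not in X_query.columns]
        if missing:
            raise SchemaError(f"query lacks descriptors: {missing}")
        cols = X_query[list(names)].to_numpy(float)
    elif isinstance(X_query, dict):
        missing = [n for n in names if n not in X_query]
        if missing:
            raise SchemaError(f"query lacks descriptors: {missing}")
        cols = np.column_stack([np.atleast_1d(np.asarray(X_query[n], float)) for n in names])
    else:
        cols = np.atleast_2d(np.asarray(X_query, float))
        if cols.shape[1] != len(names):
            raise SchemaError(f"query has {cols.shape[1]} columns, model expects {len(names)}")
    beta = np.array([model.coefficients[n] for n in names])
    return model.intercept + cols @ beta


# ---------------------------------------------------------------------------
# Subset selection


@dataclass(frozen=True)
class GAParams:
    population: int = 50
    generations: int = 100
    mutation_rate: float = 0.05
    elitism: int = 2
    tournament: int = 3


def _loo_press(A: np.ndarray, y: np.ndarray) -> float:
    # Hat-matrix shortcut: e_(-i) = e_i / (1 - h_ii).
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    residuals = y - A @ beta
    hat = np.einsum("ij,ji->i", A, np.linalg.pinv(A))
    return float(((residuals / (1.0 - hat)) ** 2).sum())


def _fitness(table: DataTable, subset: tuple[str, ...], kind: str) -> float:
    A = design_matrix(table, subset)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return -np.inf
    y = table.y
    tss = float(((y - y.mean()) ** 2).sum())
    if kind == "r2":
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((y - A @ beta) ** 2).sum())
        return 1.0 - rss / tss
    if kind == "q2_loo":
        return 1.0 - _loo_press(A, y) / tss
    raise SchemaError(f"unknown fitness {kind!r}")


def select_subset(
    table: DataTable,
    k: int,
    method: str = "exhaustive",
    fitness: str = "q2_loo",
    ga_params: GAParams | None = None,
    seed: int | None = None,
    top: int = 10,
) -> list[tuple[tuple[str, ...], float]]:
    """Rank descriptor subsets of size k by fitness (descending).

    ``exhaustive`` scans all C(p, k) subsets (guarded at 1e5); ``ga`` runs a
    seeded genetic algorithm with tournament selection, uniform crossover,
    bit-flip mutation and fixed-k repair, with elitism so the best fitness
    never decreases across generations.
    """
    p = len(table.descriptor_names)
    if k > p:
        raise SizeError(f"k={k} exceeds descriptor count {p}")
    names = table.descriptor_names

    if method == "exhaustive":
        import math

        if math.comb(p, k) > 100_000:
            raise SizeError(f"C({p},{k}) too large for exhaustive search")
        scored = [
            (subset, _fitness(table, subset, fitness))
            for subset in itertools.combinations(names, k)
        ]
        scored.sort(key=lambda item: item[1], reverse=True)
        return scored[:top]

    if method != "ga":
        raise SchemaError(f"unknown selection method {method!r}")
    if seed is None:
        raise SchemaError("GA selection requires an explicit seed")
    params = ga_params or GAParams()
    rng = np.random.default_rng(seed)

    def random_chromosome() -> frozenset:
        return frozenset(rng.choice(p, size=k, replace=False).tolist())

    def repair(genes: set) -> frozenset:
        genes = set(genes)
        while len(genes) > k:
            genes.remove(int(rng.choice(sorted(genes))))
        while len(genes) < k:
            genes.add(int(rng.integers(p)))
        return frozenset(genes)

    cache: dict[frozenset, float] = {}

    def score(chromosome: frozenset) -> float:
        if chromosome not in cache:
            subset = tuple(names[i] for i in sorted(chromosome))
            cache[chromosome] = _fitness(table, subset, fitness)
        return cache[chromosome]

    population = [random_chromosome() for _ in range(params.population)]
    for _ in range(params.generations):
        ranked = sorted(population, key=score, reverse=True)
        next_pop = ranked[: params.elitism]
        while len(next_pop) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.choice(len(population), size=params.tournament, replace=False)
                parents.append(max((population[i] for i in contenders), key=score))
            child = {
                g
                for g in parents[0] | parents[1]
                if (g in parents[0] and g in parents[1]) or rng.random() < 0.5
            }
            child = {g for g in child if rng.random() >= params.mutation_rate} | {
                int(rng.integers(p)) for _ in range(rng.binomial(k, params.mutation_rate))
            }
            next_pop.append(repair(child))
        population = next_pop

    ranked = sorted(set(population) | set(cache), key=score, reverse=True)
    return [
        (tuple(names[i] for i in sorted(ch)), score(ch)) for ch in ranked[:top]
    ]
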