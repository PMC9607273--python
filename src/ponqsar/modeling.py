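"""Descriptor preselection, train/test split and GA-MLR subset search.

The modelling chain mirrors standard QSAR practice: constant and highly
correlated descriptor columns are removed, compounds are split 80:20 by
taking every fifth compound in descending response order as test, and a
genetic algorithm searches fixed-size descriptor subsets scored by
leave-one-out Q² of the ordinary-least-squares fit.

The two published four-descriptor hydrolysis-rate models (one per PON1
isozyme) ship as JSON fixtures and load through
:func:`load_fixture_model`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .descriptors import DescriptorMatrix

__all__ = [
    "MLRModel",
    "GAConfig",
    "ModelingError",
    "drop_correlated",
    "ordered_split",
    "fit_mlr",
    "predict",
    "ga_select",
    "load_fixture_model",
]


class ModelingError(ValueError):
    pass


# ----------------------------------------------------------------- models


@dataclass
class MLRModel:
    """An intercept + linear descriptor terms, with training metadata."""

    intercept: float
    terms: list[tuple[str, float]]
    response_name: str = "response"
    train_ids: list[str] | None = None
    fit_seed: int | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ModelingError("duplicate descriptor names in model terms")
        self.terms = [(str(n), float(c)) for n, c in self.terms]

    @property
    def descriptor_names(self) -> list[str]:
        return [n for n, _ in self.terms]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms])

    @property
    def n_descriptors(self) -> int:
        return len(self.terms)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["terms"] = [[n, c] for n, c in self.terms]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            intercept=float(d["intercept"]),
            terms=[(n, float(c)) for n, c in d["terms"]],
            response_name=d.get("response_name", "response"),
            train_ids=d.get("train_ids"),
            fit_seed=d.get("fit_seed"),
            provenance=d.get("provenance", "fitted"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MLRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_fixture_model(isozyme: Literal["Q", "R"]) -> MLRModel:
    """The packaged published model for one isozyme (not refitted)."""
    if isozyme not in ("Q", "R"):
        raise ModelingError(f"isozyme must be 'Q' or 'R', got {isozyme!r}")
    fname = "model_q.json" if isozyme == "Q" else "model_r.json"
    with resources.as_file(
        resources.files("ponqsar.data").joinpath(fname)
    ) as p:
        return MLRModel.from_json(p)


# ----------------------------------------------------------- preprocessing


def drop_correlated(
    matrix: DescriptorMatrix, threshold: float = 0.95
) -> DescriptorMatrix:
    """Remove constant columns, then one of each |r| > threshold pair.

    Columns are scanned in original order; when a pair exceeds the
    threshold the later column is dropped, so the survivor of a
    correlated block is its first member.
    """
    if not 0 < threshold <= 1:
        raise ModelingError("threshold must be in (0, 1]")
    if matrix.shape[1] < 2:
        raise ModelingError("need at least 2 descriptor columns")
    sd = matrix.values.std(axis=0)
    keep_nonconst = [i for i in range(matrix.shape[1]) if sd[i] > 0]
    x = matrix.values[:, keep_nonconst]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    kept: list[int] = []
    for j in range(x.shape[1]):
        if all(abs(corr[i, j]) <= threshold for i in kept):
            kept.append(j)
    names = [matrix.descriptor_names[keep_nonconst[j]] for j in kept]
    return matrix.subset(names)


def ordered_split(
    responses: Sequence[float], period: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Every ``period``-th compound by descending response goes to test.

    Positions are 1-based after sorting (period, 2·period, ...).  Ties
    keep original row order.  Returns (train_indices, test_indices) as
    arrays of original row positions, each sorted ascending.
    """
    y = np.asarray(responses, dtype=float)
    if period < 2:
        raise ModelingError("period must be >= 2")
    if np.any(np.isnan(y)):
        raise ModelingError("responses contain NaN")
    n = len(y)
    if n < period:
        warnings.warn(
            f"n={n} < period={period}: test set is empty", stacklevel=2
        )
        return np.arange(n), np.array([], dtype=int)
    order = np.argsort(-y, kind="stable")  # descending, ties by row order
    positions = np.arange(1, n + 1)
    is_test = positions % period == 0
    test = np.sort(order[is_test])
    train = np.sort(order[~is_test])
    return train, test


# ------------------------------------------------------------ OLS fitting


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(
    X: np.ndarray | DescriptorMatrix,
    y: Sequence[float],
    names: Sequence[str] | None = None,
    response_name: str = "response",
    train_ids: Sequence[str] | None = None,
) -> MLRModel:
    """Ordinary least squares with intercept.

    Raises on rank deficiency, naming the offending columns when they
    can be identified (zero variance or duplicated direction).
    """
    if isinstance(X, DescriptorMatrix):
        if names is None:
            names = X.descriptor_names
        if train_ids is None:
            train_ids = X.compound_ids
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n < p + 2:
        raise ModelingError(f"need at least p+2={p + 2} rows, got {n}")
    d = _design(X)
    rank = np.linalg.matrix_rank(d)
    if rank < p + 1:
        bad = [names[j] for j in range(p) if X[:, j].std() == 0.0]
        if not bad:
            corr = np.corrcoef(X, rowvar=False)
            bad = sorted(
                {
                    names[j]
                    for i in range(p)
                    for j in range(i + 1, p)
                    if abs(corr[i, j]) > 1 - 1e-10
                }
            )
        raise ModelingError(
            "rank-deficient design matrix"
            + (f"; collinear column(s): {', '.join(bad)}" if bad else "")
        )
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    return MLRModel(
        intercept=float(beta[0]),
        terms=list(zip(names, beta[1:].tolist())),
        response_name=response_name,
        train_ids=list(train_ids) if train_ids is not None else None,
    )


def predict(
    model: MLRModel, matrix: DescriptorMatrix | np.ndarray
) -> np.ndarray:
    """Evaluate the model: ŷ = intercept + Σ coef·x."""
    if isinstance(matrix, DescriptorMatrix):
        missing = [
            n for n in model.descriptor_names
            if n not in matrix.descriptor_names
        ]
        if missing:
            raise ModelingError(
                f"descriptor column(s) missing from matrix: "
                f"{', '.join(missing)}"
            )
        x = np.column_stack(
            [matrix.column(n) for n in model.descriptor_names]
        )
    else:
        x = np.asarray(matrix, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != model.n_descriptors:
            raise ModelingError(
                f"expected {model.n_descriptors} columns, got {x.shape[1]}"
            )
    return model.intercept + x @ model.coefficients


# -------------------------------------------------------------- GA search


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters for descriptor-subset search.

    Defaults are a desk-scale configuration: tournament selection (k=3),
    uniform crossover, light per-gene mutation, single elitism, fitness
    = leave-one-out Q² of the OLS fit on the training compounds.
    """

    population_size: int = 50
    generations: int = 200
    model_size: int = 4
    crossover_prob: float = 0.5
    mutation_prob: float | None = None  # default 2 / n_columns
    fitness: Literal["Q2LOO", "R2"] = "Q2LOO"
    tournament_k: int = 3
    elitism: int = 1
    seed: int = 0

    def validate(self, n_rows: int, n_cols: int) -> None:
        if self.population_size < 2:
            raise ModelingError("population_size must be >= 2")
        if not 1 <= self.model_size < n_rows - 1:
            raise ModelingError(
                f"model_size must be in [1, n_rows-2]={n_rows - 2}"
            )
        if self.model_size >= n_cols:
            raise ModelingError(
                f"model_size {self.model_size} needs more than "
                f"{n_cols} descriptor columns"
            )
        if self.generations < 1:
            raise ModelingError("generations must be >= 1")


@dataclass
class RankedModel:
    model: MLRModel
    fitness: float
    descriptor_names: tuple[str, ...]


def _subset_fitness(
    X: np.ndarray, y: np.ndarray, cols: tuple[int, ...], criterion: str
) -> float:
    # local import: validation depends only on numpy, no cycle at run time
    from .validation import q2_loo, fit_metrics

    sub = X[:, list(cols)]
    try:
        if criterion == "Q2LOO":
            return q2_loo(sub, y)[0]
        d = _design(sub)
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        return fit_metrics(y, d @ beta, p=sub.shape[1]).r2
    except (ModelingError, np.linalg.LinAlgError, ValueError):
        return -np.inf


def ga_select(
    matrix: DescriptorMatrix,
    y: Sequence[float],
    config: GAConfig | None = None,
    n_models: int = 10,
    response_name: str = "response",
) -> list[RankedModel]:
    """GA search over fixed-size descriptor subsets.

    Deterministic given ``config.seed``.  Returns the best distinct
    subsets found during the whole run, ranked by fitness (descending),
    each refitted as an :class:`MLRModel`.
    """
    cfg = config or GAConfig()
    X = matrix.values
    y = np.asarray(y, dtype=float)
    n, ncols = X.shape
    cfg.validate(n, ncols)
    k = cfg.model_size
    pmut = cfg.mutation_prob if cfg.mutation_prob is not None else 2.0 / ncols
    rng = np.random.default_rng(cfg.seed)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key not in cache:
            cache[key] = _subset_fitness(X, y, key, cfg.fitness)
        return cache[key]

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(ncols, size=k, replace=False)))

    def tournament(pop, fits) -> tuple[int, ...]:
        idx = rng.integers(0, len(pop), size=cfg.tournament_k)
        best = max(idx, key=lambda i: fits[i])
        return pop[best]

    def crossover(a, b) -> tuple[int, ...]:
        # uniform on the set representation: keep the intersection, fill
        # the remaining slots from the symmetric difference at random
        common = sorted(set(a) & set(b))
        pool = sorted(set(a) ^ set(b))
        need = k - len(common)
        pick = rng.choice(len(pool), size=need, replace=False)
        return tuple(sorted(common + [pool[i] for i in pick]))

    def mutate(cols) -> tuple[int, ...]:
        # bit-flip on the column-inclusion mask (expected pmut·ncols
        # flips per child), then repair back to exactly k columns
        mask = np.zeros(ncols, dtype=bool)
        mask[list(cols)] = True
        flips = rng.random(ncols) < pmut
        mask ^= flips
        on = np.flatnonzero(mask)
        off = np.flatnonzero(~mask)
        while len(on) > k:
            drop = rng.integers(0, len(on))
            off = np.append(off, on[drop])
            on = np.delete(on, drop)
        while len(on) < k:
            add = rng.integers(0, len(off))
            on = np.append(on, off[add])
            off = np.delete(off, add)
        return tuple(sorted(int(i) for i in on))

    population = [random_subset() for _ in range(cfg.population_size)]
    fits = [fitness(c) for c in population]
    for _ in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        next_pop = [population[i] for i in order[: cfg.elitism]]
        while len(next_pop) < cfg.population_size:
            parent_a = tournament(population, fits)
            if rng.random() < cfg.crossover_prob:
                parent_b = tournament(population, fits)
                child = crossover(parent_a, parent_b)
            else:
                child = parent_a
            next_pop.append(mutate(child))
        population = next_pop
        fits = [fitness(c) for c in population]

    ranked_keys = sorted(cache, key=lambda c: cache[c], reverse=True)
    out = []
    for cols in ranked_keys[:n_models]:
        if not np.isfinite(cache[cols]):
            continue
        names = [matrix.descriptor_names[j] for j in cols]
        model = fit_mlr(
            X[:, list(cols)],
            y,
            names=names,
            response_name=response_name,
            train_ids=matrix.compound_ids,
        )
        model.fit_seed = cfg.seed
        out.append(
            RankedModel(
                model=model,
                fitness=cache[cols],
                descriptor_names=tuple(names),
            )
        )
    return out
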