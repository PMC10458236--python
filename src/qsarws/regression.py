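"""OLS regression, leave-one-out machinery, the QUIK collinearity rule, and
genetic-algorithm variable subset selection (GA-VSS).

The model family is deliberately plain: multiple linear regression with an
intercept, fitted by ordinary least squares.  What makes the workflow work
is the search on top of it — an exhaustive scan of all two-descriptor
models followed by a per-size genetic algorithm that uses the leave-one-out
cross-validated Q2 as its fitness, with candidates failing the QUIK
collinearity rule discarded outright.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    QsarError,
    SearchError,
    SingularDesignError,
    UndefinedStatisticError,
)


@dataclasses.dataclass
class MLRModel:
    """A fitted multiple linear regression y = intercept + X @ coefficients."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    n_train: int
    fitted_values: np.ndarray
    residuals: np.ndarray
    X_train: np.ndarray
    y_train: np.ndarray
    training_ids: list[str] | None = None

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    @property
    def descriptor_cap_ok(self) -> bool:
        """True when p is below one-fifth of the training-set size, the
        conventional guard against chance correlation."""
        return self.p < self.n_train / 5

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.descriptor_names)
        if X.shape[1] != self.p:
            raise QsarError(
                f"model expects {self.p} descriptors, got {X.shape[1]} columns"
            )
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "descriptor_names": self.descriptor_names,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "n_train": self.n_train,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _as_matrix(X, names: Sequence[str] | None = None) -> np.ndarray:
    """Accept an ndarray, DataFrame, or DescriptorTable-like object."""
    if hasattr(X, "descriptors"):  # DescriptorTable
        X = X.descriptors
    if isinstance(X, pd.DataFrame):
        if names is not None:
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise QsarError(f"missing descriptor column(s): {missing}")
            X = X.loc[:, list(names)]
        return X.to_numpy(float)
    return np.asarray(X, dtype=float)


def fit_ols(
    X,
    y,
    descriptor_names: Sequence[str] | None = None,
    training_ids: Sequence[str] | None = None,
) -> MLRModel:
    """Fit an intercept-including OLS regression of y on the columns of X."""
    X = _as_matrix(X, descriptor_names)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise QsarError(f"need more than p+1={p + 1} training compounds, got {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(p)]
    return MLRModel(
        descriptor_names=list(descriptor_names),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n_train=n,
        fitted_values=fitted,
        residuals=y - fitted,
        X_train=X,
        y_train=y,
        training_ids=list(training_ids) if training_ids is not None else None,
    )


# -- leave-one-out -----------------------------------------------------------


def press_residuals(X, y) -> np.ndarray:
    """Deleted (leave-one-out) residuals e_i / (1 - h_ii).

    The identity gives, for each compound, the prediction error of the model
    refitted without that compound, at a fraction of the cost of n refits.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    # hat diagonal via QR: h_ii = row norms of Q
    q, _ = np.linalg.qr(design)
    h = np.sum(q * q, axis=1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if np.any(h >= 1.0 - 1e-12):
        raise UndefinedStatisticError(
            "a leverage of 1 makes the deleted residual undefined"
        )
    return resid / (1.0 - h)


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS/TSS."""
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 2:
        raise QsarError("leave-one-out needs n > p + 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("response has zero variance")
    press = float(np.sum(press_residuals(X, y) ** 2))
    return 1.0 - press / tss


# -- QUIK rule ---------------------------------------------------------------


def k_index(M) -> float:
    """Multivariate K correlation index of a column block.

    Defined from the eigenvalues lambda_j of the correlation matrix of the
    m columns as  sum_j |lambda_j/sum(lambda) - 1/m| / (2(m-1)/m).
    0 for mutually orthogonal columns, 1 for perfectly collinear ones.
    A single column has K = 0 by convention.
    """
    M = _as_matrix(M)
    m = M.shape[1]
    if m < 2:
        return 0.0
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise UndefinedStatisticError("zero-variance column in K-index block")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    return float(np.sum(np.abs(lam / total - 1.0 / m)) / (2.0 * (m - 1) / m))


def quik_check(X, y, delta: float = 0.05) -> tuple[bool, float, float]:
    """QUIK rule: the descriptor block *plus the response* must be more
    correlated than the descriptor block alone.

    Returns ``(passed, K_XY, K_X)`` where passed iff K_XY - K_X >= delta.
    A candidate with redundant descriptors inflates K_X toward K_XY and
    fails.  Single-descriptor candidates pass trivially (K of one column is
    0 by convention, so the rule carries no information).
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if X.shape[1] < 2:
        return True, float("nan"), 0.0
    try:
        kx = k_index(X)
        kxy = k_index(np.hstack([X, y]))
    except UndefinedStatisticError:
        return False, float("nan"), float("nan")
    return (kxy - kx) >= delta, kxy, kx


# -- GA variable subset selection --------------------------------------------


@dataclasses.dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset search.

    The three headline parameters (generations per size, population size,
    mutation rate in percent) default to 2000 / 200 / 20.  The remaining
    mechanics — tournament selection of size 2, uniform crossover, elitism
    of 1 — are fixed conventions of this implementation.
    """

    max_subset_size: int
    generations_per_size: int = 2000
    population_size: int = 200
    mutation_rate_pct: float = 20.0
    quik_delta: float = 0.05
    apply_quik: bool = True
    rng_seed: int = 0
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.max_subset_size < 2:
            raise QsarError("max_subset_size must be at least 2")
        if min(self.generations_per_size, self.population_size) < 1:
            raise QsarError("GA sizes must be positive")
        if not (0 <= self.mutation_rate_pct <= 100):
            raise QsarError("mutation rate is a percentage")


@dataclasses.dataclass
class SubsetResult:
    """One scored descriptor subset from the search."""

    names: tuple[str, ...]
    q2_loo: float
    model: MLRModel


def _score_subset(subset, pool: pd.DataFrame, y, cfg: GAConfig, cache) -> float:
    key = tuple(sorted(subset))
    if key in cache:
        return cache[key]
    X = pool.loc[:, list(key)].to_numpy(float)
    try:
        if cfg.apply_quik and len(key) >= 2:
            ok, _, _ = quik_check(X, y, cfg.quik_delta)
            if not ok:
                cache[key] = -np.inf
                return -np.inf
        score = q2_loo(X, y)
    except (SingularDesignError, UndefinedStatisticError):
        score = -np.inf
    cache[key] = score
    return score


def ga_vss(pool, y, config: GAConfig) -> dict[int, list[SubsetResult]]:
    """Search descriptor subsets per size, ranked by leave-one-out Q2.

    Size 2 is explored exhaustively (all pairs).  Each larger size runs a
    genetic algorithm seeded from the best smaller subsets: tournament
    selection on Q2_LOO, uniform crossover over the union of the parents,
    per-gene mutation at ``mutation_rate_pct`` percent, elitism of one.
    Candidates failing the QUIK rule are discarded (fitness -inf).

    Returns a mapping subset size -> top_k results sorted by Q2_LOO
    (descending, ties broken by descriptor names for determinism).
    """
    if hasattr(pool, "descriptors"):
        pool = pool.descriptors
    if not isinstance(pool, pd.DataFrame):
        pool = pd.DataFrame(
            np.asarray(pool, float),
            columns=[f"x{j}" for j in range(np.asarray(pool).shape[1])],
        )
    y = np.asarray(y, dtype=float)
    names = list(pool.columns)
    if len(names) < 2:
        raise SearchError("descriptor pool must contain at least 2 columns")
    if config.max_subset_size > len(names):
        raise SearchError("max_subset_size exceeds the descriptor pool")
    n_train = len(y)
    if not config.max_subset_size < n_train / 5:
        raise SearchError(
            f"max_subset_size must stay below n_train/5 = {n_train / 5:.1f} "
            "to limit chance correlation"
        )

    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple, float] = {}
    results: dict[int, list[SubsetResult]] = {}

    def rank(subsets) -> list[tuple[str, ...]]:
        scored = [
            (s, _score_subset(s, pool, y, config, cache))
            for s in {tuple(sorted(s)) for s in subsets}
        ]
        scored = [(s, q) for s, q in scored if np.isfinite(q)]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return [s for s, _ in scored]

    def finalize(size: int, ranked: list[tuple[str, ...]]) -> None:
        top = []
        for s in ranked[: config.top_k]:
            model = fit_ols(pool.loc[:, list(s)], y, descriptor_names=list(s))
            top.append(SubsetResult(names=s, q2_loo=cache[s], model=model))
        results[size] = top

    # exhaustive scan of all two-descriptor models
    pairs = list(itertools.combinations(names, 2))
    ranked = rank(pairs)
    if not ranked:
        raise SearchError("no valid two-descriptor model (all failed QUIK/fit)")
    finalize(2, ranked)

    for size in range(3, config.max_subset_size + 1):
        population = _seed_population(
            ranked, names, size, config.population_size, rng
        )
        best = max(population, key=lambda s: _score_subset(s, pool, y, config, cache))
        for _ in range(config.generations_per_size):
            new_pop = [best]  # elitism of 1
            while len(new_pop) < config.population_size:
                p1 = _tournament(population, pool, y, config, cache, rng)
                p2 = _tournament(population, pool, y, config, cache, rng)
                child = _crossover(p1, p2, size, rng)
                child = _mutate(child, names, config.mutation_rate_pct / 100.0, rng)
                new_pop.append(child)
            population = new_pop
            gen_best = max(
                population, key=lambda s: _score_subset(s, pool, y, config, cache)
            )
            if _score_subset(gen_best, pool, y, config, cache) > _score_subset(
                best, pool, y, config, cache
            ):
                best = gen_best
        ranked = rank(
            [s for s in cache if len(s) == size and np.isfinite(cache[s])]
        )
        if not ranked:
            results[size] = []
            continue
        finalize(size, ranked)
    return results


def _seed_population(prev_ranked, names, size, pop_size, rng):
    """Grow the previous size's best subsets by one descriptor; pad randomly."""
    population: list[tuple[str, ...]] = []
    for s in prev_ranked[: pop_size // 2]:
        extras = [n for n in names if n not in s]
        if not extras:
            continue
        add = extras[rng.integers(len(extras))]
        population.append(tuple(sorted((*s, add))))
    while len(population) < pop_size:
        idx = rng.choice(len(names), size=size, replace=False)
        population.append(tuple(sorted(names[i] for i in idx)))
    return population


def _tournament(population, pool, y, cfg, cache, rng):
    i, j = rng.integers(len(population)), rng.integers(len(population))
    a, b = population[i], population[j]
    return (
        a
        if _score_subset(a, pool, y, cfg, cache)
        >= _score_subset(b, pool, y, cfg, cache)
        else b
    )


def _crossover(p1, p2, size, rng):
    union = sorted(set(p1) | set(p2))
    if len(union) <= size:
        return tuple(union) if len(union) == size else tuple(sorted(p1))
    idx = rng.choice(len(union), size=size, replace=False)
    return tuple(sorted(union[i] for i in idx))


def _mutate(subset, names, rate, rng):
    genes = list(subset)
    outside = [n for n in names if n not in subset]
    for i in range(len(genes)):
        if outside and rng.random() < rate:
            j = rng.integers(len(outside))
            genes[i], outside[j] = outside[j], genes[i]
    return tuple(sorted(genes))
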