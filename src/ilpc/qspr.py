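"""QSPR workflow for quantitative enthalpy-of-fusion modelling.

The chain is the standard OECD-style one: a deterministic training /
validation split, genetic-algorithm selection of a small descriptor subset,
an ordinary multiple linear regression on that subset, and the usual
goodness-of-fit (R², RMSE), robustness (Q²_LOO) and external predictivity
(Q²_ext, RMSE_ext) statistics, plus a leverage-based applicability domain
with the conventional warning threshold h* = 3(p+1)/n.

Split rule: records are sorted by response value and every third one,
starting from the second, goes to validation.  This keeps both extremes in
training, so the validation set never extrapolates the calibrated range.

Q²_LOO is computed by the exact hat-matrix shortcut — the leave-one-out
residual of an OLS fit is e_i / (1 − h_ii) — with an explicit refit path
(:func:`q2_loo_explicit`) kept for cross-checking; the two agree to
machine precision on any full-rank design.

The GA works on fixed-size descriptor subsets: tournament-free rank
selection, uniform subset crossover, point mutation swapping one member for
an outside descriptor, and elitism (the best individual always survives),
with Q²_LOO of the subset's MLR as fitness.  :func:`exhaustive_select`
enumerates all subsets and is practical for pools up to a dozen or so.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QSPRModel:
    descriptors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray      # kJ/mol per descriptor unit
    r2: float
    rmse_train: float
    q2_loo: float | None = None
    q2_ext: float | None = None
    rmse_ext: float | None = None
    leverage_threshold: float | None = None   # h* = 3(p+1)/n_train

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xm = _design(X, self.descriptors)
        return self.intercept + Xm @ self.coefficients


@dataclass(frozen=True)
class ADReport:
    leverages: np.ndarray
    inside: np.ndarray            # bool, h <= h*
    threshold: float
    std_residuals: np.ndarray | None = None


@dataclass(frozen=True)
class GAConfig:
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    seed: int = 0


def split_dataset(records: pd.DataFrame, response: str
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort by response; every third record (2nd, 5th, ...) to validation.

    The first and last records after sorting always stay in training, so the
    validation set never extrapolates the calibrated response range.
    """
    if len(records) < 6:
        raise ValueError(f"need at least 6 records to split, got {len(records)}")
    ordered = records.sort_values(response, kind="mergesort").reset_index(drop=True)
    idx = np.arange(len(ordered))
    val_mask = (idx % 3 == 1) & (idx < len(ordered) - 1)
    return ordered[~val_mask].reset_index(drop=True), ordered[val_mask].reset_index(drop=True)


def _design(X, names: tuple[str, ...] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise KeyError(f"design matrix missing descriptor(s) {missing}")
            X = X[list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _check_collinearity(Xm: np.ndarray, names: tuple[str, ...]) -> None:
    A = np.column_stack([np.ones(len(Xm)), Xm])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        p = Xm.shape[1]
        for i, j in itertools.combinations(range(p), 2):
            r = np.corrcoef(Xm[:, i], Xm[:, j])[0, 1]
            if abs(r) > 1 - 1e-12:
                raise ValueError(
                    f"singular design: descriptors {names[i]!r} and {names[j]!r} "
                    f"are collinear (r={r:+.6f})")
        raise ValueError("singular design matrix (collinear with intercept)")


def fit_mlr(X: pd.DataFrame | np.ndarray, y: np.ndarray,
            names: tuple[str, ...] | None = None) -> QSPRModel:
    """Ordinary least squares with intercept; training R² and RMSE."""
    Xm = _design(X, names)
    if names is None:
        names = (tuple(X.columns) if isinstance(X, pd.DataFrame)
                 else tuple(f"x{i}" for i in range(Xm.shape[1])))
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    _check_collinearity(Xm, names)
    A = np.column_stack([np.ones(n), Xm])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    return QSPRModel(descriptors=tuple(names), intercept=float(beta[0]),
                     coefficients=beta[1:], r2=r2,
                     rmse_train=float(np.sqrt(sse / n)),
                     leverage_threshold=3.0 * (p + 1) / n)


def _hat_diagonal(A: np.ndarray) -> np.ndarray:
    # h_ii via the pseudo-inverse; A must be full column rank
    return np.einsum("ij,ji->i", A, np.linalg.pinv(A))


def q2_loo(X: pd.DataFrame | np.ndarray, y: np.ndarray,
           names: tuple[str, ...] | None = None) -> float:
    """Leave-one-out Q² = 1 − PRESS/TSS via the exact hat-matrix shortcut."""
    Xm = _design(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 2:
        raise ValueError(f"too few observations for LOO (n={n}, p={p})")
    A = np.column_stack([np.ones(n), Xm])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    h = _hat_diagonal(A)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("a training point has leverage 1; LOO undefined")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def q2_loo_explicit(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> float:
    """Q²_LOO by n explicit refits (cross-check for the shortcut)."""
    Xm = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        A = np.column_stack([np.ones(n - 1), Xm[keep]])
        beta, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        pred = beta[0] + Xm[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def external_validation(model: QSPRModel, Xv: pd.DataFrame | np.ndarray,
                        yv: np.ndarray, y_train: np.ndarray,
                        train_index=None, val_index=None
                        ) -> tuple[float, float]:
    """Q²_ext = 1 − Σ(ŷ−y)² / Σ(y−ȳ_train)² and RMSE on the external set."""
    if train_index is not None and val_index is not None:
        overlap = set(train_index) & set(val_index)
        if overlap:
            raise ValueError(f"training and validation sets overlap: {sorted(overlap)[:5]}")
    yv = np.asarray(yv, dtype=float)
    pred = model.predict(Xv)
    sse = float(np.sum((pred - yv) ** 2))
    denom = float(np.sum((yv - np.mean(np.asarray(y_train, dtype=float))) ** 2))
    q2_ext = 1.0 - sse / denom
    return q2_ext, float(np.sqrt(sse / len(yv)))


def _fitness(X: pd.DataFrame, y: np.ndarray, subset: tuple[str, ...]) -> float:
    try:
        return q2_loo(X[list(subset)], y)
    except (ValueError, np.linalg.LinAlgError):
        return -np.inf


def exhaustive_select(X: pd.DataFrame, y: np.ndarray, model_size: int
                      ) -> tuple[tuple[str, ...], float]:
    """Best Q²_LOO subset by full enumeration (pools up to ~12)."""
    best, best_fit = None, -np.inf
    for combo in itertools.combinations(sorted(X.columns), model_size):
        fit = _fitness(X, y, combo)
        if fit > best_fit:
            best, best_fit = combo, fit
    return best, best_fit


def ga_select(X: pd.DataFrame, y: np.ndarray, model_size: int,
              config: GAConfig | None = None, seed: int | None = None
              ) -> tuple[tuple[str, ...], float, list[float]]:
    """Genetic-algorithm subset selection maximizing Q²_LOO.

    Returns (selected names, fitness, per-generation best-fitness trace).
    Fully reproducible from the seed.  Model sizes above n/5 raise, per the
    usual parsimony recommendation (override by slicing the pool yourself).
    """
    cfg = config or GAConfig()
    if seed is not None:
        cfg = GAConfig(cfg.population, cfg.generations, cfg.crossover_rate,
                       cfg.mutation_rate, seed)
    pool = sorted(X.columns)
    if model_size > len(pool):
        raise ValueError(f"model_size {model_size} exceeds pool of {len(pool)}")
    if model_size > len(y) / 5:
        raise ValueError(
            f"model_size {model_size} exceeds the parsimony bound n/5 = {len(y) / 5:.1f}")
    rng = np.random.default_rng(cfg.seed)

    def random_individual() -> tuple[str, ...]:
        return tuple(sorted(map(str, rng.choice(pool, size=model_size, replace=False))))

    def mutate(ind: tuple[str, ...]) -> tuple[str, ...]:
        members = list(ind)
        outside = [g for g in pool if g not in ind]
        if not outside:
            return ind
        members[rng.integers(len(members))] = outside[rng.integers(len(outside))]
        return tuple(sorted(members))

    def crossover(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
        union = sorted(set(a) | set(b))
        pick = rng.choice(union, size=model_size, replace=False)
        return tuple(sorted(map(str, pick)))

    population = [random_individual() for _ in range(cfg.population)]
    cache: dict[tuple[str, ...], float] = {}

    def fitness(ind: tuple[str, ...]) -> float:
        if ind not in cache:
            cache[ind] = _fitness(X, y, ind)
        return cache[ind]

    trace: list[float] = []
    best = max(population, key=fitness)
    trace.append(fitness(best))
    for _ in range(cfg.generations):
        ranked = sorted(population, key=fitness, reverse=True)
        parents = ranked[: max(2, cfg.population // 2)]
        children: list[tuple[str, ...]] = [ranked[0]]  # elitism
        while len(children) < cfg.population:
            a, b = parents[rng.integers(len(parents))], parents[rng.integers(len(parents))]
            child = crossover(a, b) if rng.random() < cfg.crossover_rate else a
            if rng.random() < cfg.mutation_rate:
                child = mutate(child)
            children.append(child)
        population = children
        gen_best = max(population, key=fitness)
        if fitness(gen_best) > fitness(best):
            best = gen_best
        trace.append(fitness(best))
    return best, fitness(best), trace


def applicability_domain(X_train: pd.DataFrame | np.ndarray, model: QSPRModel,
                         X_query: pd.DataFrame | np.ndarray,
                         y_query: np.ndarray | None = None,
                         y_train: np.ndarray | None = None) -> ADReport:
    """Leverages of query points against the training design.

    h_q = x_qᵀ (XᵀX)⁻¹ x_q with intercept-augmented rows; inside ⇔ h ≤ h*.
    Standardized residuals are reported when observed responses are given.
    """
    Xt = _design(X_train, model.descriptors)
    Xq = _design(X_query, model.descriptors)
    n = len(Xt)
    At = np.column_stack([np.ones(n), Xt])
    gram = At.T @ At
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("singular X'X; applicability domain undefined")
    gram_inv = np.linalg.inv(gram)
    Aq = np.column_stack([np.ones(len(Xq)), Xq])
    h = np.einsum("ij,jk,ik->i", Aq, gram_inv, Aq)
    hstar = model.leverage_threshold
    std_resid = None
    if y_query is not None:
        resid = np.asarray(y_query, dtype=float) - model.predict(X_query)
        if y_train is not None:
            train_resid = np.asarray(y_train, dtype=float) - model.predict(X_train)
            s = float(np.sqrt(np.sum(train_resid ** 2)
                              / (n - len(model.descriptors) - 1)))
        else:
            s = model.rmse_train
        std_resid = resid / s if s > 0 else np.zeros_like(resid)
    return ADReport(leverages=h, inside=h <= hstar, threshold=hstar,
                    std_residuals=std_resid)
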