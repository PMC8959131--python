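"""Objective feature selection, OLS fitting, Q2_LOO, and the GA subset search.

The model is a plain multilinear regression
``pKi = b0 + sum_j b_j * d_j`` over a small, fixed-size descriptor subset.
Subset selection is a genetic algorithm whose fitness is the leave-one-out
cross-validated explained variance Q2_LOO of the OLS fit — the response never
enters the objective (pre-)filter, only the subjective GA stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MLRModel",
    "GAParams",
    "objective_filter",
    "fit_mlr",
    "hat_diagonal",
    "q2_loo",
    "press_loo",
    "ga_select",
]


@dataclass
class MLRModel:
    """Fitted multilinear regression model (intercept + named coefficients)."""

    intercept: float
    coefficients: dict[str, float]
    n_train: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Affine evaluation; DataFrame columns are matched by name."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.descriptor_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing descriptor column(s): {missing}")
            X = X[self.descriptor_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        beta = np.array([self.coefficients[c] for c in self.descriptor_names])
        return self.intercept + X @ beta

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n_train": self.n_train,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MLRModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            coefficients=dict(payload["coefficients"]),
            n_train=payload.get("n_train", 0),
            metadata=payload.get("metadata", {}),
        )


def objective_filter(
    matrix: pd.DataFrame,
    near_constant_tol: float = 1e-8,
    corr_max: float = 0.90,
    identical_fraction: float = 0.95,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Response-blind descriptor pruning.

    Removes columns that are constant, near-constant (modal value in at least
    ``identical_fraction`` of rows, or variance below ``near_constant_tol``),
    or correlated beyond ``corr_max`` in absolute Pearson r with an
    already-retained column. Columns are scanned in alphabetical order, so for
    a correlated pair the alphabetically-first member survives; the removal
    log is fully deterministic.
    """
    log: list[tuple[str, str]] = []
    survivors_nc = []
    for name in matrix.columns:
        col = matrix[name].to_numpy()
        nunique = len(np.unique(col))
        if nunique == 1:
            log.append((name, "constant"))
            continue
        mode_frac = pd.Series(col).value_counts(normalize=True).iloc[0]
        if mode_frac >= identical_fraction:
            log.append((name, f"near-constant ({mode_frac:.0%} identical)"))
            continue
        if float(np.var(col)) < near_constant_tol:
            log.append((name, "near-constant (variance below tolerance)"))
            continue
        survivors_nc.append(name)
    kept: list[str] = []
    for name in sorted(survivors_nc):
        col = matrix[name].to_numpy()
        partner = None
        for other in kept:
            r = np.corrcoef(col, matrix[other].to_numpy())[0, 1]
            if abs(r) > corr_max:
                partner = other
                break
        if partner is None:
            kept.append(name)
        else:
            log.append((name, f"|r| > {corr_max:g} with {partner}"))
    if not kept:
        raise ValueError("objective filter removed every descriptor column")
    # preserve the original column order among survivors
    kept_ordered = [c for c in matrix.columns if c in set(kept)]
    return matrix[kept_ordered], log


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(X: pd.DataFrame | np.ndarray, y: np.ndarray,
            names: list[str] | None = None) -> MLRModel:
    """Ordinary least squares via QR on the intercept-augmented design.

    Raises on rank deficiency, naming the dependent columns where possible.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    # identically-zero columns carry no information: they get coefficient 0
    # rather than tripping the rank check
    zero_cols = [j for j in range(p) if not np.any(X[:, j])]
    if zero_cols:
        live = [j for j in range(p) if j not in zero_cols]
        sub = fit_mlr(X[:, live], y, names=[names[j] for j in live]) if live else \
            MLRModel(intercept=float(y.mean()), coefficients={}, n_train=n)
        coefs = {names[j]: 0.0 for j in range(p)}
        coefs.update(sub.coefficients)
        return MLRModel(intercept=sub.intercept,
                        coefficients={names[j]: coefs[names[j]] for j in range(p)},
                        n_train=n)
    A = _design(X)
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        # identify offending columns by incremental rank growth
        bad = []
        cols = [A[:, 0]]
        for j in range(p):
            cand = np.column_stack(cols + [A[:, j + 1]])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(names[j])
            else:
                cols.append(A[:, j + 1])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MLRModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        n_train=n,
    )


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix H = A (A'A)^-1 A' for the intercept-augmented
    design, computed stably from the thin QR factor."""
    A = _design(np.asarray(X, dtype=float))
    q, _ = np.linalg.qr(A)
    return np.einsum("ij,ij->i", q, q)


def press_loo(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out PRESS via the closed form e_i / (1 - h_ii)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = _design(X)
    q, r = np.linalg.qr(A)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,ij->i", q, q)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a training point has leverage 1; cannot leave it out")
    loo_resid = resid / (1.0 - h)
    return float(loo_resid @ loo_resid)


def q2_loo(X: np.ndarray | pd.DataFrame, y: np.ndarray) -> float:
    """Leave-one-out cross-validated explained variance, 1 - PRESS/TSS."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance")
    return 1.0 - press_loo(X, y) / tss


@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters for fixed-size subset selection."""

    population_size: int = 64
    generations: int = 300
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    elitism: int = 2
    subset_size: int = 6
    seed: int = 0
    patience: int | None = None  # optional stop after this many stagnant generations

    def validate(self, n_columns: int) -> None:
        if min(self.population_size, self.generations, self.subset_size) < 1:
            raise ValueError("population, generations and subset size must be >= 1")
        if self.subset_size > n_columns:
            raise ValueError(
                f"subset size {self.subset_size} exceeds descriptor count {n_columns}"
            )
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def _repair(subset: set[int], size: int, n: int, rng: np.random.Generator) -> frozenset[int]:
    subset = set(subset)
    while len(subset) > size:
        subset.remove(rng.choice(sorted(subset)))
    pool = [i for i in range(n) if i not in subset]
    while len(subset) < size:
        pick = pool.pop(rng.integers(len(pool)))
        subset.add(pick)
    return frozenset(subset)


def ga_select(
    matrix: pd.DataFrame,
    y: np.ndarray,
    params: GAParams | None = None,
) -> tuple[list[str], MLRModel, list[float]]:
    """GA-MLR descriptor subset search with Q2_LOO fitness.

    Chromosomes are fixed-size descriptor subsets. Each generation applies
    tournament-of-3 selection, uniform subset crossover repaired back to the
    fixed size, single-gene swap mutation, and elitism. Returns the best-ever
    subset (column names), its refitted model on the full input, and the
    best-so-far fitness trace (one value per generation, non-decreasing).
    """
    params = params or GAParams()
    n_cols = matrix.shape[1]
    params.validate(n_cols)
    Xall = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(params.seed)
    cache: dict[frozenset[int], float] = {}

    def fitness(subset: frozenset[int]) -> float:
        if subset not in cache:
            idx = sorted(subset)
            try:
                cache[subset] = q2_loo(Xall[:, idx], y)
            except (ValueError, np.linalg.LinAlgError):
                cache[subset] = -np.inf
        return cache[subset]

    pop = [
        frozenset(rng.choice(n_cols, size=params.subset_size, replace=False).tolist())
        for _ in range(params.population_size)
    ]
    best: frozenset[int] | None = None
    best_fit = -np.inf
    trace: list[float] = []
    stagnant = 0
    for _gen in range(params.generations):
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best = pop[gen_best]
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if params.patience is not None and stagnant >= params.patience:
            break
        # elitism: carry the current top individuals unchanged
        elite_order = np.argsort(fits)[::-1][: params.elitism]
        nxt: list[frozenset[int]] = [pop[i] for i in elite_order]
        while len(nxt) < params.population_size:
            contestants = rng.integers(0, params.population_size, size=(2, 3))
            pa = pop[contestants[0][np.argmax(fits[contestants[0]])]]
            pb = pop[contestants[1][np.argmax(fits[contestants[1]])]]
            if rng.random() < params.crossover_prob:
                union = sorted(pa | pb)
                mask = rng.random(len(union)) < 0.5
                child = {g for g, m in zip(union, mask) if m}
                child = _repair(child, params.subset_size, n_cols, rng)
            else:
                child = pa
            if rng.random() < params.mutation_prob:
                child = set(child)
                child.remove(rng.choice(sorted(child)))
                pool = [i for i in range(n_cols) if i not in child]
                child.add(pool[rng.integers(len(pool))])
                child = frozenset(child)
            nxt.append(child)
        pop = nxt
    assert best is not None
    selected = [names[i] for i in sorted(best)]
    model = fit_mlr(matrix[selected], y)
    model.metadata.update(
        {"fitness_q2_loo": best_fit, "ga_seed": params.seed,
         "generations_run": len(trace)}
    )
    return selected, model, trace
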