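"""Training-population update policies and optimization criteria.

Each cycle, 150 selection candidates are phenotyped and added to the
training data.  Policies: Top / Bottom / Tails (ranked by predicted value),
Random, PEVmean and CDmean (exchange-optimized phenotyping sets), and
No Change.  Two composition scenarios govern what happens afterwards:
Cumulative keeps everything; Window holds the training population at a fixed
size by discarding lines from the oldest cycle present.

PEVmean minimizes the mean prediction error variance of contrasts between
target individuals (the 100 chosen parents) and the population mean;
CDmean maximizes the mean generalized coefficient of determination
(expected reliability) of those contrasts.  Both derive from the inverse
mixed-model coefficient matrix K = Z'MZ + lambda A^{-1}, where Z is the
incidence of the proposed phenotyping set on the candidate pool, M the
grand-mean projector, A the pool's base-scaled genomic relationship
(ridge-stabilized), and lambda = sigma2_e / sigma2_a from the current
cycle's REML fit:

    PEV(c) = sigma2_e * c' K^{-1} c / c'c
    CD(c)  = c' [A − lambda K^{-1}] c / c' A c

Evaluation never inverts A: with G = A_r / lambda and U the centered rows
of G at the phenotyped subset, a Woodbury identity reduces K^{-1} to
G − G U'(I + U G U')^{-1} U G, whose inner solve is only
n_phenotyped × n_phenotyped.  This is what makes 500 greedy exchange
iterations per cycle affordable; tests pin its equality to the explicit
mixed-model-equation inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .gp_engine import MarkerEffects, TrainingSet

METHODS = ("top", "bottom", "tails", "random", "pevmean", "cdmean", "nochange")
ACTIVE_METHODS = tuple(m for m in METHODS if m != "nochange")


@dataclass
class UpdateMethod:
    """A named update policy with its knobs."""

    name: str
    n_add: int = 150
    exchange_iterations: int = 500

    def __post_init__(self):
        if self.name not in METHODS:
            raise ValueError(f"unknown update method {self.name!r}; "
                             f"choose from {METHODS}")
        if self.name == "tails" and self.n_add % 2:
            raise ValueError("tails requires an even n_add")
        if self.n_add < 0 or self.exchange_iterations < 0:
            raise ValueError("counts must be non-negative")


def build_contrasts(target_indices, pool_size: int) -> np.ndarray:
    """Contrast matrix between each target and the whole-pool mean.

    Column t is ``indicator(target t) − 1/pool_size``; every column sums to
    zero.  A single-member pool is rejected (the contrast degenerates to the
    zero vector).
    """
    targets = np.asarray(target_indices, dtype=np.int64)
    if targets.size == 0:
        raise ValueError("need at least one target")
    if np.any(targets < 0) or np.any(targets >= pool_size):
        raise ValueError("target indices must lie inside the pool")
    if pool_size < 2:
        raise ValueError("pool of one gives a degenerate (zero) contrast")
    C = np.full((pool_size, targets.size), -1.0 / pool_size)
    C[targets, np.arange(targets.size)] += 1.0
    return C


@dataclass
class OptimizationContext:
    """Fixed quantities of one cycle's PEV/CD optimization problem."""

    A: np.ndarray            # pool × pool genomic relationship
    sigma2_e: float
    sigma2_a: float
    C: np.ndarray            # pool × n_targets contrasts
    ridge: float = 1e-6
    _cache: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.C.shape[0] != n:
            raise ValueError("contrast rows must match the pool size")
        if self.sigma2_a <= 0 or self.sigma2_e < 0:
            raise ValueError("variances must be positive (sigma2_a) / "
                             "non-negative (sigma2_e)")

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_a

    def _prepared(self):
        if not self._cache:
            n = self.A.shape[0]
            A_r = self.A + self.ridge * float(np.diag(self.A).mean()) * np.eye(n)
            G = A_r / self.lambda_
            GC = G @ self.C
            self._cache.update(
                A_r=A_r, G=G, GC=GC,
                diag_CC=(self.C * self.C).sum(axis=0),
                diag_CGC=(self.C * GC).sum(axis=0),
                diag_CAC=(self.C * (A_r @ self.C)).sum(axis=0),
            )
            if np.any(self._cache["diag_CAC"] <= 0):
                raise ValueError("a target contrast is orthogonal to A "
                                 "(zero CD denominator)")
        return self._cache


def _solve_quadratic(ctx: OptimizationContext, phenotyped) -> np.ndarray:
    """diag[(TC)' S^{-1} (TC)] per contrast for the given phenotyping set."""
    cache = ctx._prepared()
    idx = np.asarray(phenotyped, dtype=np.int64)
    if idx.size == 0:
        return np.zeros(ctx.C.shape[1])
    B = cache["GC"][idx, :]
    B = B - B.mean(axis=0)
    Gs = cache["G"][np.ix_(idx, idx)]
    rm = Gs.mean(axis=1, keepdims=True)
    cm = Gs.mean(axis=0, keepdims=True)
    S = Gs - rm - cm + Gs.mean()
    S[np.diag_indices(len(idx))] += 1.0
    W = linalg.solve(S, B, assume_a="pos", check_finite=False)
    return (B * W).sum(axis=0)


def pev_of_contrasts(ctx: OptimizationContext, phenotyped) -> np.ndarray:
    """Prediction error variance of each target contrast, normalized by c'c."""
    cache = ctx._prepared()
    q = _solve_quadratic(ctx, phenotyped)
    return ctx.sigma2_e * (cache["diag_CGC"] - q) / cache["diag_CC"]


def cd_of_contrasts(ctx: OptimizationContext, phenotyped) -> np.ndarray:
    """Generalized coefficient of determination (reliability) per contrast."""
    cache = ctx._prepared()
    q = _solve_quadratic(ctx, phenotyped)
    return ctx.lambda_ * q / cache["diag_CAC"]


def _criterion_value(criterion: str, ctx: OptimizationContext, subset) -> float:
    if criterion == "pevmean":
        return float(pev_of_contrasts(ctx, subset).mean())
    if criterion == "cdmean":
        return float(cd_of_contrasts(ctx, subset).mean())
    raise ValueError(f"unknown criterion {criterion!r}")


def exchange_optimize(criterion: str, ctx: OptimizationContext,
                      pool_size: int, n_select: int = 150,
                      iterations: int = 500,
                      rng: np.random.Generator | None = None,
                      return_trajectory: bool = False):
    """Greedy 1-for-1 exchange search for a phenotyping subset.

    Starts from a uniform random subset of ``n_select`` pool members; each
    iteration proposes swapping one random selected member with one random
    unselected member and accepts only strict improvements (lower PEVmean /
    higher CDmean).  Returns the incumbent subset after ``iterations``
    proposals (and the accepted-criterion trajectory on request).
    """
    if n_select > pool_size:
        raise ValueError("n_select exceeds the pool")
    rng = rng or np.random.default_rng()
    selected = rng.choice(pool_size, size=n_select, replace=False)
    minimize = criterion == "pevmean"
    value = _criterion_value(criterion, ctx, selected)
    trajectory = [value]
    if n_select < pool_size:
        unselected = np.setdiff1d(np.arange(pool_size), selected)
        for _ in range(iterations):
            i = int(rng.integers(n_select))
            j = int(rng.integers(len(unselected)))
            proposal = selected.copy()
            proposal[i] = unselected[j]
            new = _criterion_value(criterion, ctx, proposal)
            if (new < value) if minimize else (new > value):
                out = selected[i]
                selected = proposal
                unselected[j] = out
                value = new
            trajectory.append(value)
    if return_trajectory:
        return np.sort(selected), np.asarray(trajectory)
    return np.sort(selected)


def _ranked_indices(predictions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Candidate indices from best to worst prediction, random tie-break."""
    g = np.asarray(predictions, dtype=float)
    perm = rng.permutation(len(g))
    return perm[np.argsort(-g[perm], kind="stable")]


def select_update_set(method: UpdateMethod | str, predictions: np.ndarray,
                      parent_indices: np.ndarray,
                      effects: MarkerEffects | None = None,
                      A_pool: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Candidate indices to phenotype and add to the training population.

    For PEVmean/CDmean the targets are the chosen parents (the proxy for the
    next cycle's unphenotyped candidates) and the sampling pool is the whole
    candidate cohort; the relationship matrix ``A_pool`` over the cohort and
    the cycle's fitted variance components are required.  ``nochange``
    returns an empty set.
    """
    if isinstance(method, str):
        method = UpdateMethod(method)
    rng = rng or np.random.default_rng()
    n_pool = len(predictions)
    if method.name == "nochange":
        return np.empty(0, dtype=np.int64)
    if method.n_add > n_pool:
        raise ValueError("n_add exceeds the candidate pool")
    if method.name == "top":
        return np.sort(_ranked_indices(predictions, rng)[:method.n_add])
    if method.name == "bottom":
        return np.sort(_ranked_indices(predictions, rng)[-method.n_add:])
    if method.name == "tails":
        ranked = _ranked_indices(predictions, rng)
        half = method.n_add // 2
        return np.sort(np.concatenate([ranked[:half], ranked[-half:]]))
    if method.name == "random":
        return np.sort(rng.choice(n_pool, size=method.n_add, replace=False))
    # criterion methods
    if effects is None or A_pool is None:
        raise ValueError(f"{method.name} requires marker effects and the "
                         "candidate-pool relationship matrix")
    ctx = OptimizationContext(
        A=A_pool, sigma2_e=effects.sigma2_e, sigma2_a=effects.sigma2_a,
        C=build_contrasts(parent_indices, n_pool))
    return exchange_optimize(method.name, ctx, n_pool,
                             n_select=method.n_add,
                             iterations=method.exchange_iterations, rng=rng)


def apply_scenario(tp: TrainingSet, additions: TrainingSet | None,
                   scenario: str = "cumulative",
                   window_size: int | None = None,
                   rng: np.random.Generator | None = None) -> TrainingSet:
    """Merge this cycle's additions into the training population.

    ``cumulative`` appends.  ``window`` appends and then discards enough
    lines to return to ``window_size`` (default: the pre-update size),
    always drawing uniformly at random from the oldest cycle present and
    moving to the next-oldest once a cycle is exhausted.
    """
    if additions is None or len(additions) == 0:
        return tp
    if scenario == "cumulative":
        return tp.append(additions)
    if scenario != "window":
        raise ValueError(f"unknown scenario {scenario!r}")
    target = len(tp) if window_size is None else window_size
    merged = tp.append(additions)
    n_drop = len(merged) - target
    if n_drop < 0:
        raise ValueError("window_size exceeds the merged training population")
    rng = rng or np.random.default_rng()
    keep = np.ones(len(merged), dtype=bool)
    while n_drop > 0:
        cycles_left = merged.cycle_of_origin[keep]
        oldest = cycles_left.min()
        members = np.flatnonzero(keep & (merged.cycle_of_origin == oldest))
        take = min(n_drop, len(members))
        drop = rng.choice(members, size=take, replace=False)
        keep[drop] = False
        n_drop -= take
    return merged.subset(np.flatnonzero(keep))
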