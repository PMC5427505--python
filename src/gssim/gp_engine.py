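"""Genomic prediction: marker filtering, RR-BLUP/REML, and parent selection.

The prediction model is ridge-regression BLUP,

    y = 1 mu + Z u + e,    u ~ N(0, I V_u),    e ~ N(0, I sigma2_e),

with y the training entry means and Z the {1, 0, −1} marker incidence
(hom first allele / het / hom second).  V_u and sigma2_e are estimated by
REML; the restricted likelihood is profiled down to a one-dimensional search
over the variance ratio delta = sigma2_e / V_u using the spectrum of the
mean-centered marker kernel, then BLUPs solve the mixed-model equations at
the REML ratio.  Candidate values are predicted as g_hat = Z_SC u_hat (no
intercept: predictions are used for ranking and correlation only).

`RRBLUP` / `RRBLUPResults` expose the fit statsmodels-style;
:func:`fit_rrblup` keeps the pipeline-facing surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genetic_arch import QTLArchitecture
from .meiosis import Population

RATIO_BOUNDS = (1e-9, 1e9)


@dataclass
class TrainingSet:
    """Phenotyped, genotyped lines accumulated over breeding cycles.

    ``Z`` holds genotypes at *all* loci (markers and QTL) in {1, 0, −1}
    coding; the QTL columns are never used for prediction (they are excluded
    by :func:`filter_markers`) but are needed for base-scaled relationship
    and LD bookkeeping.
    """

    line_ids: np.ndarray
    Z: np.ndarray                # n_lines × n_loci, int8 {1, 0, −1}
    y: np.ndarray                # entry means
    cycle_of_origin: np.ndarray  # per line

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.Z = np.asarray(self.Z, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.cycle_of_origin = np.asarray(self.cycle_of_origin, dtype=np.int64)
        if not (len(self.line_ids) == len(self.Z) == len(self.y)
                == len(self.cycle_of_origin)):
            raise ValueError("training-set fields must have equal row counts")
        if np.any(self.cycle_of_origin < 0):
            raise ValueError("cycle_of_origin must be non-negative")

    def __len__(self) -> int:
        return len(self.y)

    def m_matrix(self) -> np.ndarray:
        """Second-allele-count-minus-one coding (used for relationships)."""
        return (-self.Z).astype(np.int8)

    def append(self, other: "TrainingSet") -> "TrainingSet":
        return TrainingSet(
            np.concatenate([self.line_ids, other.line_ids]),
            np.vstack([self.Z, other.Z]),
            np.concatenate([self.y, other.y]),
            np.concatenate([self.cycle_of_origin, other.cycle_of_origin]),
        )

    def subset(self, indices) -> "TrainingSet":
        idx = np.asarray(indices)
        return TrainingSet(self.line_ids[idx], self.Z[idx], self.y[idx],
                           self.cycle_of_origin[idx])


@dataclass
class MarkerEffects:
    """Fitted RR-BLUP solution for one cycle's retained markers."""

    mu: float
    u_hat: np.ndarray
    V_u: float
    sigma2_e: float
    retained: np.ndarray  # locus indices the effects refer to

    @property
    def sigma2_a(self) -> float:
        """Additive genetic variance: number of markers × V_u."""
        return len(self.u_hat) * self.V_u

    def to_frame(self, marker_ids=None) -> pd.DataFrame:
        ids = (np.asarray(marker_ids)[self.retained]
               if marker_ids is not None else self.retained)
        return pd.DataFrame({"marker_id": ids, "u_hat": self.u_hat})

    def header(self) -> dict:
        return {"mu": self.mu, "V_u": self.V_u, "sigma2_e": self.sigma2_e,
                "sigma2_a": self.sigma2_a, "N_m": len(self.u_hat)}


def _maf(Z: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column; heterozygotes count one half."""
    freq2 = (1.0 - Z.mean(axis=0, dtype=np.float64)) / 2.0
    return np.minimum(freq2, 1.0 - freq2)


def filter_markers(tp: TrainingSet, candidates: Population,
                   arch: QTLArchitecture, maf_min: float = 0.03) -> np.ndarray:
    """Indices of loci usable for prediction this cycle.

    QTL are always excluded (markers are assayed, causal loci are not).  A
    marker is retained only if it is polymorphic with MAF ≥ ``maf_min`` in
    the training population *and* in the candidate pool — failing in either
    removes it.
    """
    n_loci = tp.Z.shape[1]
    if candidates.n_loci != n_loci:
        raise ValueError("training set and candidates must share the locus set")
    maf_tp = _maf(tp.Z)
    maf_sc = _maf(candidates.z_matrix())
    keep = (maf_tp >= maf_min) & (maf_sc >= maf_min) \
        & (maf_tp > 0) & (maf_sc > 0)
    keep[arch.qtl_indices] = False
    retained = np.flatnonzero(keep)
    if len(retained) == 0:
        raise ValueError("no markers retained after filtering")
    return retained


class RRBLUP:
    """Ridge-regression BLUP model with a grand mean and i.i.d. marker effects."""

    def __init__(self, y: np.ndarray, Z: np.ndarray):
        self.y = np.asarray(y, dtype=np.float64)
        self.Z = np.asarray(Z, dtype=np.float64)
        if self.Z.ndim != 2 or len(self.y) != self.Z.shape[0]:
            raise ValueError("y and Z must have matching row counts")
        if len(self.y) < 2:
            raise ValueError("need at least two training lines")
        if self.Z.shape[1] < 1:
            raise ValueError("need at least one marker")

    # restricted log-likelihood, profiled over V_u, as a function of delta
    def _spectrum(self):
        y, Z = self.y, self.Z
        n = len(y)
        yc = y - y.mean()
        Zc = Z - Z.mean(axis=0)
        sv = linalg.svd(Zc, compute_uv=True, full_matrices=False)
        U, s = sv[0], sv[1]
        tol = s.max(initial=0.0) * max(Zc.shape) * np.finfo(float).eps
        r = int((s > tol).sum())
        theta = s[:r] ** 2
        eta2 = (U[:, :r].T @ yc) ** 2
        rem = float(yc @ yc - eta2.sum())
        rem = max(rem, 0.0)
        return theta, eta2, rem, n - 1, r

    @staticmethod
    def _neg_reml(log_delta, theta, eta2, rem, q, r):
        d = np.exp(log_delta)
        f = float((eta2 / (theta + d)).sum() + rem / d)
        logdet = float(np.log(theta + d).sum() + (q - r) * np.log(d))
        return 0.5 * (q * np.log(2.0 * np.pi * f / q) + q + logdet)

    def fit(self, ratio_bounds=RATIO_BOUNDS, grid_points: int = 121) -> "RRBLUPResults":
        y, Z = self.y, self.Z
        n, m = Z.shape
        if np.ptp(y) == 0.0:  # degenerate: no signal at all
            return RRBLUPResults(self, mu=float(y[0]), u_hat=np.zeros(m),
                                 V_u=0.0, sigma2_e=0.0, delta=ratio_bounds[1],
                                 reml_loglik=np.nan)
        theta, eta2, rem, q, r = self._spectrum()
        args = (theta, eta2, rem, q, r)
        lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
        grid = np.linspace(lo, hi, grid_points)
        vals = np.array([self._neg_reml(g, *args) for g in grid])
        k = int(np.argmin(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid_points - 1)]
        res = optimize.minimize_scalar(
            self._neg_reml, bounds=(a, b), args=args, method="bounded",
            options={"xatol": 1e-10})
        log_d = float(res.x) if res.fun <= vals[k] else float(grid[k])
        delta = float(np.exp(log_d))
        f = float((eta2 / (theta + delta)).sum() + rem / delta)
        V_u = f / q
        sigma2_e = delta * V_u

        # BLUP solution at the REML ratio; use the smaller of the two
        # equivalent linear systems (m × m markers or n × n kernel)
        if m <= n:
            ZtZ = Z.T @ Z
            ZtZ[np.diag_indices(m)] += delta
            cf = linalg.cho_factor(ZtZ, lower=True, check_finite=False)

            def h_inv(v):  # (ZZ' + delta I)^{-1} v via Woodbury
                return (v - Z @ linalg.cho_solve(cf, Z.T @ v,
                                                 check_finite=False)) / delta

            w1 = h_inv(np.ones(n))
            wy = h_inv(y)
            mu = float(np.ones(n) @ wy) / float(np.ones(n) @ w1)
            u = linalg.cho_solve(cf, Z.T @ (y - mu), check_finite=False)
        else:
            K = Z @ Z.T
            K[np.diag_indices(n)] += delta
            cf = linalg.cho_factor(K, lower=True, check_finite=False)
            w1 = linalg.cho_solve(cf, np.ones(n), check_finite=False)
            wy = linalg.cho_solve(cf, y, check_finite=False)
            mu = float(np.ones(n) @ wy) / float(np.ones(n) @ w1)
            u = Z.T @ linalg.cho_solve(cf, y - mu, check_finite=False)
        loglik = -self._neg_reml(log_d, *args)
        return RRBLUPResults(self, mu=mu, u_hat=np.asarray(u), V_u=V_u,
                             sigma2_e=sigma2_e, delta=delta,
                             reml_loglik=float(loglik))


@dataclass
class RRBLUPResults:
    """REML variance components and BLUP marker effects."""

    model: RRBLUP
    mu: float
    u_hat: np.ndarray
    V_u: float
    sigma2_e: float
    delta: float            # sigma2_e / V_u at the REML optimum
    reml_loglik: float

    @property
    def sigma2_a(self) -> float:
        return self.model.Z.shape[1] * self.V_u

    def predict(self, Z_new: np.ndarray, include_mean: bool = False) -> np.ndarray:
        g = np.asarray(Z_new, dtype=np.float64) @ self.u_hat
        return g + self.mu if include_mean else g

    def restricted_loglik(self, delta: float) -> float:
        """Profile restricted log-likelihood at an arbitrary variance ratio."""
        theta, eta2, rem, q, r = self.model._spectrum()
        return -RRBLUP._neg_reml(np.log(delta), theta, eta2, rem, q, r)

    def summary(self) -> str:
        n, m = self.model.Z.shape
        lines = [
            "RR-BLUP (REML) results",
            "=" * 38,
            f"{'training lines':<24}{n:>14d}",
            f"{'markers':<24}{m:>14d}",
            f"{'grand mean (mu)':<24}{self.mu:>14.5g}",
            f"{'V_u (marker var)':<24}{self.V_u:>14.5g}",
            f"{'sigma2_e (residual)':<24}{self.sigma2_e:>14.5g}",
            f"{'sigma2_a (= m * V_u)':<24}{self.sigma2_a:>14.5g}",
            f"{'delta (ratio)':<24}{self.delta:>14.5g}",
            f"{'restricted loglik':<24}{self.reml_loglik:>14.5g}",
        ]
        return "\n".join(lines)


def fit_rrblup(tp: TrainingSet, retained: np.ndarray) -> MarkerEffects:
    """Fit RR-BLUP on the retained markers of a training set."""
    res = RRBLUP(tp.y, tp.Z[:, retained]).fit()
    return MarkerEffects(mu=res.mu, u_hat=res.u_hat, V_u=res.V_u,
                         sigma2_e=res.sigma2_e, retained=np.asarray(retained))


def predict_genotypic_values(effects: MarkerEffects, candidates: Population,
                             retained: np.ndarray | None = None) -> np.ndarray:
    """g_hat = Z_SC u_hat over the retained markers (no intercept)."""
    ret = effects.retained if retained is None else np.asarray(retained)
    Z_sc = candidates.z_matrix()[:, ret].astype(np.float64)
    return Z_sc @ effects.u_hat


def select_parents(predictions: np.ndarray, n_parents: int = 100,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Indices of the candidates with the highest predicted values.

    Ties are broken uniformly at random using ``rng`` (deterministic under
    the replicate's seeded stream).
    """
    g = np.asarray(predictions, dtype=float)
    if n_parents > len(g):
        raise ValueError("n_parents exceeds the candidate pool")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(len(g))
    order = perm[np.argsort(-g[perm], kind="stable")]
    return order[:n_parents]
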