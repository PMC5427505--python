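"""Per-cycle tracked variables of the breeding simulation.

Relationships are base-scaled (VanRaden): with p_i the second-allele
frequency at locus i in the base population, genotypes coded as
second-allele count − 1 are centered by P = 2(p_i − 0.5) and the
cross-product is normalized by c = 2 Σ p_i (1 − p_i), so A = W W' / c.
P and c are computed once from the base population and frozen for the whole
replicate; inbreeding is diag(A) − 1.  Persistence of LD phase between two
populations (the "correlation of r") correlates their QTL × marker LD
matrices over the loci polymorphic in both.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .genetic_arch import QTLArchitecture


@dataclass
class RelationshipContext:
    """Base-population centering vector and normalization constant."""

    P: np.ndarray  # per locus: 2 (p_i − 0.5)
    c: float       # 2 Σ p_i (1 − p_i)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.c <= 0:
            raise ValueError("normalization constant must be positive")


def build_relationship_context(base) -> RelationshipContext:
    """Freeze P and c from the base population (panel or population)."""
    p = base.dosage().mean(axis=0) / 2.0  # second-allele frequency
    c = float(2.0 * np.sum(p * (1.0 - p)))
    return RelationshipContext(P=2.0 * (p - 0.5), c=c)


def _w(M: np.ndarray, ctx: RelationshipContext) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.shape[1] != len(ctx.P):
        raise ValueError("locus mismatch between genotypes and context")
    return M - ctx.P


def relationship_matrix(M: np.ndarray, ctx: RelationshipContext) -> np.ndarray:
    """A = W W' / c for genotypes coded as second-allele count − 1."""
    W = _w(M, ctx)
    return (W @ W.T) / ctx.c


def self_relationship(M: np.ndarray, ctx: RelationshipContext) -> np.ndarray:
    """diag(A) without forming A (cheap for large cohorts)."""
    W = _w(M, ctx)
    return (W * W).sum(axis=1) / ctx.c


def mean_cross_relationship(M1: np.ndarray, M2: np.ndarray,
                            ctx: RelationshipContext) -> float:
    """Mean of the A block between two cohorts, without forming A."""
    W1, W2 = _w(M1, ctx), _w(M2, ctx)
    return float(W1.mean(axis=0) @ W2.mean(axis=0)) / ctx.c


def mean_tp_sc_relationship(A: np.ndarray, tp_indices, sc_indices) -> float:
    """Mean relationship over the TP × candidate rectangle of A."""
    tp_idx = np.asarray(tp_indices)
    sc_idx = np.asarray(sc_indices)
    if tp_idx.size == 0 or sc_idx.size == 0:
        raise ValueError("index sets must be non-empty")
    return float(A[np.ix_(tp_idx, sc_idx)].mean())


def inbreeding_coefficients(A: np.ndarray, indices=None) -> np.ndarray:
    """diag(A) − 1 for the requested individuals."""
    d = np.diag(A) if indices is None else np.diag(A)[np.asarray(indices)]
    return d - 1.0


def prediction_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation between predicted and true genotypic values."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(true, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")  # undefined: no variation in one of the vectors
    return float(np.corrcoef(x, y)[0, 1])


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    return Xc / sd


def ld_phase_persistence(M_a: np.ndarray, M_b: np.ndarray,
                         arch: QTLArchitecture) -> float:
    """Correlation of QTL–marker LD correlations between two populations.

    For each population, r between every QTL and every marker is computed on
    genotype dosages; loci monomorphic in either population are excluded
    (both correlations must exist).  The two flattened r matrices are then
    correlated.  Symmetric in its population arguments.

    Dosage columns are first oriented to the pooled minor allele, so the
    metric does not depend on the arbitrary allele labelling of the input
    (a consistent label flip leaves the value exactly unchanged).
    """
    M_a = np.asarray(M_a, dtype=np.float64)
    M_b = np.asarray(M_b, dtype=np.float64)
    if M_a.shape[1] != M_b.shape[1]:
        raise ValueError("populations must share the locus set")
    pooled = np.vstack([M_a, M_b]).mean(axis=0)
    orient = np.where(pooled > 0, -1.0, 1.0)
    M_a = M_a * orient
    M_b = M_b * orient
    n_loci = M_a.shape[1]
    poly = (M_a.std(axis=0) > 0) & (M_b.std(axis=0) > 0)
    qtl_mask = np.zeros(n_loci, dtype=bool)
    qtl_mask[arch.qtl_indices] = True
    q_idx = np.flatnonzero(poly & qtl_mask)
    m_idx = np.flatnonzero(poly & ~qtl_mask)
    if len(q_idx) * len(m_idx) < 2:
        raise ValueError("fewer than two shared polymorphic QTL-marker pairs")
    flat = []
    for M in (M_a, M_b):
        Q = _standardize_columns(M[:, q_idx])
        K = _standardize_columns(M[:, m_idx])
        r = (Q.T @ K) / M.shape[0]
        flat.append(r.ravel())
    return float(np.corrcoef(flat[0], flat[1])[0, 1])


def n_qtl_fixed(dosage: np.ndarray, arch: QTLArchitecture) -> int:
    """QTL with a single allele present in the cohort (het counts as both)."""
    q = np.asarray(dosage)[:, arch.qtl_indices]
    return int(np.sum((q.max(axis=0) == 0) | (q.min(axis=0) == 2)))


@dataclass
class CycleMetrics:
    """One record per cycle per replicate of every tracked variable."""

    cycle: int
    accuracy: float
    genetic_variance: float
    mean_genotypic_value: float
    mean_tp_sc_relationship: float
    mean_inbreeding: float
    ld_phase_persistence: float
    n_qtl_fixed: int
    n_markers_retained: int
    tp_size: int
    n_candidates: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cycle(state) -> CycleMetrics:
    """Assemble the full metrics record from a completed cycle state.

    ``state`` provides: cycle, candidates (Population), predictions, true_g,
    tp (TrainingSet, pre-update), retained (marker indices), arch, rel_ctx.
    """
    cand_dosage = state.candidates.dosage()
    cand_M = cand_dosage.astype(np.int16) - 1
    tp_M = state.tp.m_matrix()
    g = np.asarray(state.true_g, dtype=float)
    return CycleMetrics(
        cycle=state.cycle,
        accuracy=prediction_accuracy(state.predictions, g),
        genetic_variance=float(np.var(g, ddof=1)),
        mean_genotypic_value=float(g.mean()),
        mean_tp_sc_relationship=mean_cross_relationship(tp_M, cand_M, state.rel_ctx),
        mean_inbreeding=float(
            (self_relationship(cand_M, state.rel_ctx) - 1.0).mean()),
        ld_phase_persistence=ld_phase_persistence(tp_M, cand_M, state.arch),
        n_qtl_fixed=n_qtl_fixed(cand_dosage, state.arch),
        n_markers_retained=len(state.retained),
        tp_size=len(state.tp),
        n_candidates=len(state.candidates),
    )
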