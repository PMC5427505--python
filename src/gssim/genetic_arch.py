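"""Trait architecture: QTL sampling, geometric effects, and phenotypes.

The simulated trait is purely additive.  ``L`` loci are drawn uniformly at
random from the panel's loci to act as causal QTL.  The k-th QTL (in sampled
order) has homozygote value ``a**k`` with ``a = (L − 1)/(L + 1)``: a
geometric series modelling a few large and many small effects.  The
favorable homozygote carries ``+a**k``, the unfavorable ``−a**k``, and the
heterozygote 0 (no dominance).  Which allele is favorable is random per QTL.

Phenotypes follow ``y_ij = g_i + e_j + eps_ij`` over ``n_env`` environments
with a single replication; entry means over environments are what the
genomic-prediction model sees.  Environment and residual variances are
calibrated once against the base population and then frozen, so heritability
drifts as genetic variance erodes over cycles of selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QTLArchitecture:
    """Which loci are causal, their favorable alleles and effect sizes."""

    qtl_indices: np.ndarray      # L locus indices into the panel's loci
    favorable_allele: np.ndarray  # per QTL: 0 = first allele, 1 = second
    effects: np.ndarray          # per QTL: a**k, k = 1..L
    base_a: float

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.favorable_allele = np.asarray(self.favorable_allele, dtype=np.int8)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ValueError("QTL indices must be unique")
        if not (len(self.qtl_indices) == len(self.favorable_allele) == len(self.effects)):
            raise ValueError("per-QTL arrays must have equal length")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    def marker_indices(self, n_loci: int) -> np.ndarray:
        """All loci that are not QTL (the markers available for prediction)."""
        mask = np.ones(n_loci, dtype=bool)
        mask[self.qtl_indices] = False
        return np.flatnonzero(mask)

    def max_genotypic_value(self) -> float:
        return float(self.effects.sum())

    def to_frame(self, gmap=None) -> pd.DataFrame:
        """CSV-ready audit table (locus index, map position, allele, effect)."""
        out = pd.DataFrame(
            {"locus_index": self.qtl_indices,
             "favorable_allele": self.favorable_allele,
             "effect": self.effects}
        )
        if gmap is not None:
            out.insert(1, "chromosome", gmap.chromosome[self.qtl_indices])
            out.insert(2, "cM", gmap.position_cM[self.qtl_indices])
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QTLArchitecture":
        """Rebuild an architecture from its audit table."""
        L = len(frame)
        return cls(frame["locus_index"].to_numpy(),
                   frame["favorable_allele"].to_numpy(),
                   frame["effect"].to_numpy(),
                   base_a=(L - 1) / (L + 1) if L > 1 else 0.0)


@dataclass
class PhenotypeModel:
    """Frozen variance components of the phenotype simulation."""

    n_env: int
    sigma2_G: float   # variance among base-population genotypic values
    sigma2_E: float   # environment main-effect variance (= 8 × sigma2_G)
    sigma2_R: float   # residual variance (within-env + GxE, confounded)
    target_h2: float  # entry-mean heritability targeted at calibration


def sample_qtl(panel_or_n_loci, L: int = 100,
               seed: int | np.random.Generator | None = None) -> QTLArchitecture:
    """Draw ``L`` QTL uniformly at random, regardless of position or MAF."""
    n_loci = (panel_or_n_loci if isinstance(panel_or_n_loci, (int, np.integer))
              else panel_or_n_loci.n_loci)
    if L > n_loci:
        raise ValueError(f"L={L} exceeds the number of loci ({n_loci})")
    if L < 1:
        raise ValueError("L must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n_loci, size=L, replace=False)
    favorable = rng.integers(0, 2, size=L).astype(np.int8)
    a = (L - 1) / (L + 1)
    effects = a ** np.arange(1, L + 1)
    return QTLArchitecture(idx, favorable, effects, a)


def genotypic_values(dosage: np.ndarray, arch: QTLArchitecture) -> np.ndarray:
    """True genotypic values for a dosage matrix (second-allele counts).

    Accepts shape ``(n, n_loci)`` or a single ``(n_loci,)`` vector.  Only QTL
    columns contribute: per QTL the favorable-allele dosage minus one is the
    sign (+1 favorable homozygote, 0 heterozygote, −1 unfavorable).
    """
    arr = np.asarray(dosage)
    d = np.atleast_2d(arr)
    q = d[:, arch.qtl_indices].astype(np.float64)
    fav = np.where(arch.favorable_allele == 1, q, 2.0 - q)
    vals = (fav - 1.0) @ arch.effects
    return vals if arr.ndim > 1 else float(vals[0])


def genotypic_value(individual, arch: QTLArchitecture) -> float:
    """Genotypic value of a single individual (or dosage vector)."""
    dosage = (individual if isinstance(individual, np.ndarray)
              else individual.haplotypes.sum(axis=0))
    return float(genotypic_values(np.asarray(dosage).ravel(), arch))


def calibrate_variances(base_genotypic_values: np.ndarray, n_env: int = 3,
                        target_h2: float = 0.5,
                        env_var_multiple: float = 8.0) -> PhenotypeModel:
    """Fix the non-genetic variances against the base population.

    ``sigma2_E = env_var_multiple × var(g)`` and ``sigma2_R`` solves the
    entry-mean heritability equation ``h2 = s2G / (s2G + s2R / n_env)``.
    Environment main effects are common to all entries and cancel out of
    entry-mean comparisons, so they do not enter the heritability identity.
    """
    g = np.asarray(base_genotypic_values, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two genotypic values")
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must lie in (0, 1)")
    if n_env < 1:
        raise ValueError("n_env must be positive")
    s2g = float(np.var(g, ddof=1))
    if s2g == 0.0:
        raise ValueError("zero genetic variance: heritability undefined")
    s2e = env_var_multiple * s2g
    s2r = n_env * s2g * (1.0 - target_h2) / target_h2
    return PhenotypeModel(n_env=n_env, sigma2_G=s2g, sigma2_E=s2e,
                          sigma2_R=s2r, target_h2=target_h2)


def simulate_phenotypes(genotypic_vals: np.ndarray, model: PhenotypeModel,
                        seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Entry means over ``n_env`` environments for the given genotypic values.

    One environment effect per environment (shared by all entries) and one
    residual per entry × environment are drawn; the per-entry mean over
    environments is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.asarray(genotypic_vals, dtype=float)
    env = rng.normal(0.0, np.sqrt(model.sigma2_E), size=model.n_env)
    eps = rng.normal(0.0, np.sqrt(model.sigma2_R), size=(g.size, model.n_env))
    y = g[:, None] + env[None, :] + eps
    return y.mean(axis=1)
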