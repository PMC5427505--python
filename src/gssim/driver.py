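"""Orchestration of the recurrent genomewide-selection experiment.

A replicate initializes the base population (synthetic founder panel or a
user-supplied one), samples the QTL architecture, calibrates the phenotype
model, selects cycle-1 parents on base-population phenotypes (top 50 per
breeding program, crossed program-vs-program), and then runs the three-step
cycle n_cycles times: develop candidates → predict and select → update the
training population.  Metrics are recorded for every cycle; the training
population size reported for a cycle is the one used for that cycle's
predictions.

Seeding is hierarchical: the master seed and replicate index spawn
independent named streams (founders, qtl, phenotype, meiosis, selection,
update, scenario), so the founder panel, QTL draw and population-development
randomness are identical across update methods within a replicate — method
contrasts are paired by common random numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import founders as fd
from . import genetic_arch as ga
from . import gp_engine as gp
from . import metrics as mt
from . import tp_update as tu
from .meiosis import Population, develop_population

logger = logging.getLogger("gssim")

STREAMS = ("founders", "qtl", "phenotype", "meiosis", "selection",
           "update", "scenario")


@dataclass
class FounderSpec:
    """Parameters of the synthetic founder panel."""

    n_lines: int = 764
    n_loci: int = 1590
    n_chromosomes: int = 7
    total_map_cM: float = 1137.0
    maf_beta_a: float = 0.5
    maf_beta_b: float = 0.5
    maf_low: float | None = None   # None: truncate at 1/n_lines resolution
    maf_high: float = 0.5
    n_subpops: int = 2
    divergence: float = 0.1
    n_ancestral_haplotypes: int = 20
    mosaic_generations: float = 5.0

    def generate(self, rng: np.random.Generator) -> fd.FounderPanel:
        return fd.generate_founder_panel(
            n_lines=self.n_lines, n_loci=self.n_loci,
            n_chromosomes=self.n_chromosomes, total_map_cM=self.total_map_cM,
            maf_spectrum=fd.beta_maf(self.maf_beta_a, self.maf_beta_b,
                                     self.maf_low, self.maf_high),
            n_subpops=self.n_subpops, divergence=self.divergence,
            seed=rng, n_ancestral_haplotypes=self.n_ancestral_haplotypes,
            mosaic_generations=self.mosaic_generations,
        )


@dataclass
class SimConfig:
    """Configuration of one simulation condition."""

    n_cycles: int = 15
    n_replicates: int = 250
    L: int = 100
    n_parents: int = 100
    n_crosses: int = 50
    lines_per_cross: int = 20
    n_add: int = 150
    maf_min: float = 0.03
    n_env: int = 3
    target_h2: float = 0.5
    env_var_multiple: float = 8.0
    exchange_iterations: int = 500
    method: str = "random"
    scenario: str = "cumulative"
    founder: FounderSpec = field(default_factory=FounderSpec)
    founder_path: str | None = None   # genotype CSV (with .map.csv sibling)
    founder_map_path: str | None = None
    master_seed: int = 0

    def __post_init__(self):
        if isinstance(self.founder, dict):
            self.founder = FounderSpec(**self.founder)
        if self.n_parents != 2 * self.n_crosses:
            raise ValueError("n_parents must equal 2 × n_crosses")
        for name in ("n_cycles", "L", "n_parents", "n_crosses",
                     "lines_per_cross", "n_add", "n_env"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.method not in tu.METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.scenario not in ("cumulative", "window"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def pool_size(self) -> int:
        return self.n_crosses * self.lines_per_cross

    @property
    def condition(self) -> str:
        return f"{self.method}-{self.scenario}"

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def replicate_streams(master_seed: int, replicate: int) -> dict[str, np.random.Generator]:
    """Named independent RNG streams for one replicate."""
    return {
        name: np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(replicate, k)))
        for k, name in enumerate(STREAMS)
    }


@dataclass
class CycleState:
    """Everything carried between cycles of one replicate."""

    config: SimConfig
    rngs: dict
    panel: fd.FounderPanel
    arch: ga.QTLArchitecture
    model: ga.PhenotypeModel
    rel_ctx: mt.RelationshipContext
    tp: gp.TrainingSet
    parents: Population
    parent_programs: np.ndarray | None = None  # cycle-1 program labels
    cycle: int = 0
    candidates: Population | None = None
    predictions: np.ndarray | None = None
    true_g: np.ndarray | None = None
    effects: gp.MarkerEffects | None = None
    retained: np.ndarray | None = None
    update_indices: np.ndarray | None = None


@dataclass
class ReplicateResult:
    """Per-cycle metrics plus the replicate's audit information."""

    metrics: list
    arch: ga.QTLArchitecture
    config: SimConfig
    replicate: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([m.to_dict() for m in self.metrics])
        df.insert(0, "replicate", self.replicate)
        df.insert(1, "method", self.config.method)
        df.insert(2, "scenario", self.config.scenario)
        df.insert(3, "condition", self.config.condition)
        return df


def _initial_state(config: SimConfig, replicate: int) -> CycleState:
    rngs = replicate_streams(config.master_seed, replicate)
    if config.founder_path is not None:
        panel = fd.load_genotype_matrix(config.founder_path,
                                        config.founder_map_path)
    else:
        panel = config.founder.generate(rngs["founders"])
    arch = ga.sample_qtl(panel, config.L, rngs["qtl"])
    base_dosage = panel.dosage()
    g_base = ga.genotypic_values(base_dosage, arch)
    model = ga.calibrate_variances(g_base, config.n_env, config.target_h2,
                                   config.env_var_multiple)
    y_base = ga.simulate_phenotypes(g_base, model, rngs["phenotype"])
    rel_ctx = mt.build_relationship_context(panel)
    tp = gp.TrainingSet(panel.line_ids, panel.z_matrix(), y_base,
                        np.zeros(panel.n_lines, dtype=np.int64))

    # cycle-1 parents: top half per program on base-population phenotypes
    per_program = config.n_parents // len(np.unique(panel.program))
    chosen = []
    for prog in np.unique(panel.program):
        rows = np.flatnonzero(panel.program == prog)
        order = tu._ranked_indices(y_base[rows], rngs["selection"])
        chosen.append(rows[order[:per_program]])
    chosen = np.concatenate(chosen)
    base_pop = Population.from_panel(panel, cycle=0)
    parents = base_pop.subset(chosen)
    return CycleState(config=config, rngs=rngs, panel=panel, arch=arch,
                      model=model, rel_ctx=rel_ctx, tp=tp, parents=parents,
                      parent_programs=panel.program[chosen])


def run_cycle(state: CycleState, config: SimConfig | None = None) -> CycleState:
    """Advance one breeding cycle: develop, predict/select, update."""
    config = config or state.config
    cycle = state.cycle + 1
    try:
        pairing = "paired" if (cycle == 1 and state.parent_programs is not None) \
            else "random"
        state.candidates = develop_population(
            state.parents, state.panel.gmap, state.rngs["meiosis"],
            n_crosses=config.n_crosses, lines_per_cross=config.lines_per_cross,
            pairing=pairing,
            programs=state.parent_programs if pairing == "paired" else None,
            cycle=cycle)
        state.retained = gp.filter_markers(state.tp, state.candidates,
                                           state.arch, config.maf_min)
        state.effects = gp.fit_rrblup(state.tp, state.retained)
        state.predictions = gp.predict_genotypic_values(state.effects,
                                                        state.candidates)
        state.true_g = ga.genotypic_values(state.candidates.dosage(),
                                           state.arch)
        parent_idx = gp.select_parents(state.predictions, config.n_parents,
                                       state.rngs["selection"])
        method = tu.UpdateMethod(config.method, n_add=config.n_add,
                                 exchange_iterations=config.exchange_iterations)
        A_pool = None
        if method.name in ("pevmean", "cdmean"):
            cand_M = state.candidates.dosage().astype(np.int16) - 1
            A_pool = mt.relationship_matrix(cand_M, state.rel_ctx)
        state.update_indices = tu.select_update_set(
            method, state.predictions, parent_idx, state.effects, A_pool,
            state.rngs["update"])
        state.cycle = cycle
        record = mt.summarize_cycle(state)  # pre-update TP size

        if len(state.update_indices):
            upd = state.candidates.subset(state.update_indices)
            y_upd = ga.simulate_phenotypes(state.true_g[state.update_indices],
                                           state.model,
                                           state.rngs["phenotype"])
            additions = gp.TrainingSet(
                upd.ids, upd.z_matrix(), y_upd,
                np.full(len(upd), cycle, dtype=np.int64))
            # window keeps the pre-update size, i.e. the base-population size
            window = len(state.tp) if config.scenario == "window" else None
            state.tp = tu.apply_scenario(state.tp, additions, config.scenario,
                                         window_size=window,
                                         rng=state.rngs["scenario"])
        state.parents = state.candidates.subset(parent_idx)
        state.parent_programs = None
        logger.info("cycle %d [%s]: accuracy=%.3f markers=%d tp=%d",
                    cycle, config.condition, record.accuracy,
                    record.n_markers_retained, record.tp_size)
        return state, record
    except Exception as exc:
        raise RuntimeError(f"cycle {cycle} [{config.condition}] failed: {exc}") from exc


def run_replicate(config: SimConfig, replicate: int = 0) -> ReplicateResult:
    """Run one full replicate (base population plus n_cycles cycles)."""
    state = _initial_state(config, replicate)
    records = []
    for _ in range(config.n_cycles):
        state, record = run_cycle(state)
        records.append(record)
    return ReplicateResult(metrics=records, arch=state.arch, config=config,
                           replicate=replicate)


def run_experiment(config: SimConfig,
                   methods=tu.METHODS,
                   scenarios=("cumulative", "window"),
                   n_replicates: int | None = None) -> pd.DataFrame:
    """Tidy per-cycle metrics over a methods × scenarios × replicates grid.

    Every method is run under every scenario (No Change included in both,
    where its trajectories are identical by construction).  Replicates are
    paired across conditions by common random numbers.
    """
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    frames = []
    failures = []
    for scenario in scenarios:
        for method in methods:
            cfg = config.replace(method=method, scenario=scenario)
            for rep in range(n_rep):
                try:
                    frames.append(run_replicate(cfg, rep).to_frame())
                except Exception as exc:  # recorded, not silently dropped
                    failures.append({"method": method, "scenario": scenario,
                                     "replicate": rep, "error": str(exc)})
                    logger.error("replicate failed: %s/%s rep %d: %s",
                                 method, scenario, rep, exc)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.attrs["failures"] = failures
    return out


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate means with 95% confidence intervals per cycle/condition."""
    value_cols = [c for c in results.columns
                  if c not in ("replicate", "method", "scenario", "condition",
                               "cycle")]
    grouped = results.groupby(["condition", "method", "scenario", "cycle"])
    rows = []
    for key, df in grouped:
        row = dict(zip(["condition", "method", "scenario", "cycle"], key))
        n = len(df)
        for col in value_cols:
            mean = df[col].mean()
            se = df[col].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            row[f"{col}_mean"] = mean
            row[f"{col}_ci95_lo"] = mean - 1.96 * se
            row[f"{col}_ci95_hi"] = mean + 1.96 * se
        row["n_replicates"] = n
        rows.append(row)
    return pd.DataFrame(rows)
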