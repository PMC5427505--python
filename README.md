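# gssim — recurrent genomewide-selection breeding simulation

`gssim` simulates a closed, inbred-line (barley-style) breeding program run
on genomic prediction, for researchers studying how the **training
population** (TP) should be maintained over many cycles of selection.  As
recombination, selection and drift reshuffle the linkage disequilibrium
(LD) between markers and QTL, prediction accuracy decays unless the TP is
refreshed — but *which* newly phenotyped lines should go in?  The simulator
compares seven update policies (Top, Bottom, Tails, Random, PEVmean,
CDmean, No Change) under two TP-composition scenarios (Cumulative growth
vs a fixed-size sliding Window), tracking accuracy, genetic gain, genetic
variance, genomic relationships, inbreeding, LD-phase persistence and
marker/QTL fixation per cycle.

## The model in brief

A trait with `L = 100` additive QTL carries geometric-series effects: QTL
`k` has homozygote values `±a^k`, heterozygote 0, with
`a = (L−1)/(L+1)`.  Phenotypes follow `y_ij = g_i + e_j + ε_ij` over three
environments, calibrated so `σ²_E = 8σ²_G` and the base-population
entry-mean heritability is `h² = 0.5`.  Marker effects are estimated by
RR-BLUP,

    y = 1μ + Zu + e,   u ~ N(0, I·V_u),   e ~ N(0, I·σ²_e),

with REML variance components, and candidates are ranked by `ĝ = Z û`.
The PEVmean/CDmean policies pick phenotyping sets by greedy exchange on
the prediction error variance `PEV(c) = σ²_e · c'K⁻¹c / c'c` or the
generalized reliability `CD(c) = c'[A − λK⁻¹]c / c'Ac`, where
`K = Z'MZ + λA⁻¹`, `λ = σ²_e/σ²_a`, and `A` is the VanRaden genomic
relationship scaled to base-population allele frequencies
(`A = WW'/c`, `W = M − P`).  A synthetic founder generator supplies
two-subpopulation inbred panels with a U-shaped MAF spectrum and realistic
LD decay; real panels load from delimited genotype + map files.

## Worked example

```python
import gssim

cfg = gssim.SimConfig(n_cycles=15, method="random", scenario="cumulative",
                      master_seed=1)
result = gssim.run_replicate(cfg, replicate=0)
df = result.to_frame()
print(df[["cycle", "accuracy", "mean_genotypic_value",
          "n_qtl_fixed", "n_markers_retained", "tp_size"]]
      .iloc[[0, 4, 9, 14]].to_string(index=False))
```

prints (one replicate, default 764 × 1590 founder panel):

```
 cycle  accuracy  mean_genotypic_value  n_qtl_fixed  n_markers_retained  tp_size
     1  0.543285              9.806291            7                1209      764
     5  0.512738             16.204176           40                 852     1364
    10  0.285129             20.657635           60                 473     2114
    15  0.046401             22.694261           84                 297     2864
```

Accuracy starts near 0.5 and decays as heritability and marker coverage
erode; the population mean rises (genetic gain); QTL progressively fix
(7 → 84 of 100) and the usable marker set shrinks (1209 → 297) as selection
and drift remove polymorphism; the Cumulative TP grows from 764 to 2864
lines.  Single replicates are noisy — `run_experiment` averages them.  The RR-BLUP fit itself is exposed statsmodels-style:

```python
from gssim import RRBLUP
res = RRBLUP(y, Z).fit()     # REML variance components + BLUP effects
print(res.summary())
ghat = res.predict(Z_candidates)
```

A full methods × scenarios grid with across-replicate summaries:

```python
df = gssim.run_experiment(cfg, n_replicates=10)     # 14 conditions
summary = gssim.summarize_experiment(df)            # means + 95% CIs
```

or from the shell:

    gssim run --method top --scenario window --replicates 10 \
              --cycles 15 --seed 42 --out results/
    gssim founders --lines 764 --loci 1590 --seed 1 --out panel
    gssim summarize results/ --out summary.csv

## Layout

- `gssim.founders` — synthetic panel generator, genotype I/O, preprocessing
- `gssim.genetic_arch` — QTL sampling, genotypic values, phenotype model
- `gssim.meiosis` — gametes, crosses, single-seed descent, cohorts
- `gssim.gp_engine` — marker filters, `RRBLUP`/REML, prediction, selection
- `gssim.tp_update` — update policies, PEV/CD criteria, exchange search,
  Cumulative/Window scenarios
- `gssim.metrics` — per-cycle tracked variables
- `gssim.driver` — cycle/replicate/experiment orchestration and seeding
- `gssim.cli` — `gssim` command-line interface

See `docs/methods.md` for modelling assumptions, numerical choices, and
what the synthetic founder data does and does not emulate.
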