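# Methods

`gssim` simulates a closed barley-style breeding program run on genomic
prediction, to study how the composition of the training population (TP)
drives long-term prediction accuracy, genetic gain, diversity and
inbreeding.  This note records the model, the choices made where the design
was genuinely open, and the limits of what the synthetic data can show.

## The breeding system

One replicate proceeds as follows.

1. **Base population (cycle 0).**  A panel of fully inbred lines from two
   breeding programs (default 764 lines, 1590 biallelic loci on 7
   chromosomes spanning 1137 cM) provides genotypes.  By default the panel
   is synthetic (below); a user panel can be loaded from delimited genotype
   + map files and cleaned with the standard filters (markers/lines with
   more than 10% missing calls dropped, redundant co-located markers
   collapsed, a 0.01 cM interval forced between co-located non-identical
   markers, heterozygous calls set to missing, modal imputation).
2. **Trait.**  `L = 100` loci are drawn uniformly at random as additive QTL.
   QTL `k` has homozygote value `a^k` with `a = (L − 1)/(L + 1) ≈ 0.980`, a
   geometric series of a few large and many small effects; heterozygotes
   are 0 (no dominance, no epistasis).  The genotypic value `g` of a line
   is the sum of its QTL allele effects.
3. **Phenotypes.**  `y_ij = g_i + e_j + ε_ij` over `n_env = 3` environments
   with one replication; entry means over environments feed the prediction
   model.  At calibration, `σ²_E = 8 σ²_G` and `σ²_R` solves the entry-mean
   heritability identity `h² = σ²_G / (σ²_G + σ²_R/n_env)` at `h² = 0.5`.
   Environment effects are shared by all entries phenotyped together, so
   they cancel from entry-mean contrasts and do not enter the identity.
   Both non-genetic variances are frozen afterwards, so realized
   heritability erodes as selection depletes genetic variance.
4. **Cycle 1.**  The top 50 lines per program on base phenotypes are
   crossed program-vs-program (50 crosses, each parent once); each cross
   yields 20 F3-derived lines by single-seed descent, giving 1000 selection
   candidates genotyped at the F3 stage (residual heterozygosity retained).
5. **Cycles 2–15.**  Parents are re-paired uniformly at random each cycle
   (each parent once).  Per cycle: markers are filtered (QTL never
   genotyped; markers monomorphic or with MAF < 0.03 in either the TP or
   the candidates dropped), RR-BLUP is fitted to the TP, candidate values
   are predicted as `ĝ = Z û`, the top 100 candidates become parents, and
   150 candidates are phenotyped and added to the TP per the update policy.

Meiosis uses a no-interference model: per chromosome, crossover counts are
Poisson(span/100) with uniform positions (Haldane map function); no
mutation.

## RR-BLUP and REML

The prediction model is `y = 1μ + Zu + e`, `u ~ N(0, I V_u)`,
`e ~ N(0, I σ²_e)`, with `Z` coded 1 / 0 / −1 (hom first allele / het / hom
second).  REML is profiled to a one-dimensional search over the variance
ratio `δ = σ²_e/V_u` using the singular spectrum of the mean-centered
marker matrix; the profile restricted likelihood is evaluated on a 121-point
log-spaced grid over `δ ∈ [1e−9, 1e9]` and refined by bounded minimization
(xatol 1e−10 in log δ).  The grid guards against the mild multimodality
single-ratio REML can exhibit.  BLUPs then solve the mixed-model equations
at the REML ratio through whichever of the two equivalent systems is
smaller (m × m marker system or n × n kernel system, linked by the
push-through identity).  A constant-`y` training set short-circuits to
`V_u = 0, û = 0, μ = y`.  `σ²_a = N_m V_u` with `N_m` the retained marker
count.

## Training-population update policies

Top / Bottom / Tails rank candidates by `ĝ` (ties broken by the replicate's
seeded stream); Random samples uniformly; No Change does nothing.  PEVmean
and CDmean choose the 150 candidates to phenotype by a greedy exchange
search (uniform random start, one random 1-for-1 swap proposed per
iteration, strict improvements accepted, 500 iterations) on criteria built
from the mixed-model coefficient matrix `K = Z'MZ + λA⁻¹`:

    PEV(c) = σ²_e · c'K⁻¹c / c'c          (minimized, mean over targets)
    CD(c)  = c'[A − λK⁻¹]c / c'Ac         (maximized, mean over targets)

where the targets `c` contrast each of the 100 chosen parents against the
candidate-pool mean, `A` is the pool's base-scaled genomic relationship,
`M` the grand-mean projector on the proposed phenotyping records, and
`λ = σ²_e/σ²_a` from the cycle's REML fit.  `A` is stabilized with a ridge
of `1e−6 × mean(diag A)` before use (inbred-line `A` can be singular).
Evaluation uses the Woodbury identity
`K⁻¹ = G − GU'(I + UGU')⁻¹UG` with `G = A_r/λ` and `U` the centered
phenotyped rows, so only a 150 × 150 system is solved per proposal and `A`
is never inverted; tests pin the equality of both criteria to the explicit
mixed-model-equation inverse at 1e−8.  One printed form of the CD
expression is ambiguous about bracket placement; the implementation follows
the generalized-reliability definition above, which the oracle identity
`CD = 1 − PEV·(c'c)/(σ²_a c'Ac)` confirms.

Two composition scenarios: **Cumulative** appends the 150 additions each
cycle (TP grows 764 → 2864); **Window** appends and then discards an equal
number of lines, always uniformly at random from the oldest cycle present
(the base population first), holding the TP at 764.

## Tracked variables

Per cycle: prediction accuracy (Pearson r between `ĝ` and true `g` of the
candidates); genetic variance and mean of true `g`; base-scaled VanRaden
relationships `A = WW'/c` with `W = M − P`, `P = 2(p_i − 0.5)` and
`c = 2Σp_i(1−p_i)` frozen from the base population (mean TP × candidate
block, and inbreeding `diag(A) − 1` of candidates); LD-phase persistence
(the correlation between the two populations' QTL × marker dosage-
correlation matrices over loci polymorphic in both — loci monomorphic in
either population are excluded because their correlation is undefined);
the number of QTL fixed among candidates; and the retained-marker count.
Large cohorts never materialize the full `A`: the TP × candidate mean and
the diagonal are computed directly from `W`.  Dosage columns are oriented
to the pooled minor allele before LD correlations, so the metric is
invariant to arbitrary allele labelling of the input.

## Synthetic founder panel

The generator emulates a two-program inbred breeding panel rather than any
particular dataset:

- **MAF spectrum**: per-locus minor-allele frequencies are drawn from
  Beta(0.5, 0.5) truncated below at the panel's frequency resolution
  (1/n_lines; a segregating variant among n inbred lines cannot be rarer)
  and above at 0.5.  The U-shape carries the rare-variant load that drives
  early fixation under a 100-parent bottleneck.
- **Spatial arrangement**: the drawn frequencies are rank-matched to an
  Ornstein–Uhlenbeck field along the map (correlation length 15 cM), so
  neighboring loci have similar frequencies, as they do on real haplotype
  structure.  Marginally the spectrum is untouched.
- **Divergence**: program allele frequencies follow a Balding–Nichols model
  with `F = 0.1` (typical of related breeding programs), sampled through a
  Gaussian copula on the same spatial field (programs diverge by haplotype
  blocks) and recentered so the panel-wide frequency equals the spectrum
  draw exactly.
- **LD**: each program descends from 20 ancestral haplotypes.  Per locus,
  exactly `round(20 p_s)` second alleles are placed on the haplotypes
  ranked highest by a per-haplotype OU score field (correlation length
  15 cM, 5% locus noise), so nearby loci share carriers and pool LD decays
  smoothly with distance.  Lines are recombination mosaics over their
  program's pool (Poisson switching at 5 × the per-meiosis rate,
  representing a few generations of admixture), fully homozygous.
- **Calibration**: after assembly, per-locus carrier counts are adjusted by
  flipping the fewest random lines needed to hit the target count
  (removals keep the carriers' shared background; additions realize
  variants rarer than the pool resolution).  Every locus is left
  polymorphic, mirroring a segregating SNP array.

Realized properties at the defaults: all-polymorphic 764 × 1590 panel,
mean adjacent-marker r² ≈ 0.15 decaying to background by ~20 cM,
within-panel MAF distribution equal to the truncated Beta draw,
between-program |Δp| increasing monotonically in `F`.

What the generator does **not** reproduce: real pedigree structure and
kinship gradients within programs, ascertainment bias of array markers,
multi-allelic or structural variation, and any particular dataset's exact
LD surface.  Passing tests therefore show that the *method pipeline*
behaves as designed under a realistic frequency/LD regime, not that its
absolute accuracy levels match any empirical program.

## Seeding and pairing of conditions

A master seed plus replicate index spawn named independent streams
(founders, qtl, phenotype, meiosis, selection, update, scenario).  Because
the update method touches only its own streams, all methods share founder
panels, QTL draws, base phenotypes and population-development randomness
within a replicate: method contrasts are paired (common random numbers),
which sharpens small-replicate comparisons.  Condition summaries report
across-replicate means with ±1.96·SE intervals.

## Problem sizes used by the test suite and acceptance script

The package's own verification runs at sizes chosen to make the full
stochastic pipeline repeatable on a single CPU: fixation dynamics use the
full default panel (764 × 1590) with 12–15 replicates of the
Random/Cumulative condition; the 14-condition policy-ordering grid runs on
a reduced panel (300 lines × 800 loci) with 3 replicates, keeping the
full-scale cohort sizes (1000 candidates, 100 parents, 150 additions, 500
exchange iterations).  Ordering conclusions are qualitative and stable at
these sizes; absolute levels carry Monte-Carlo error of a few points.

## Known limitations

- Single trait, purely additive; no dominance, epistasis, GxE (beyond the
  confounded residual), mutation, or crossover interference.
- Random mating among selected parents; no mate allocation or repeated use
  of elite parents across cycles.
- The exchange search is greedy with a fixed iteration budget; it matches
  exhaustive search on small instances (tested) but is not guaranteed
  optimal at 1000-choose-150.
- REML assumes i.i.d. residuals; phenotyping-campaign environment offsets
  shared within a cycle's additions are real correlated noise the model
  absorbs imperfectly — deliberately so, as part of the simulated design.
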