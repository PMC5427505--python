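"""Founder panels: synthetic generation, genotype I/O, and preprocessing.

The base population of the simulated breeding program is a panel of fully
inbred (homozygous) lines from two breeding programs, genotyped at biallelic
loci placed on a genetic map.  A panel can either be generated synthetically —
a mosaic-haplotype construction that emulates the long-range linkage
disequilibrium of a real breeding panel — or loaded from delimited genotype
and map files and cleaned with :func:`preprocess_panel`.

Allele coding throughout the package: haplotype entries are ``0`` (first
allele) or ``1`` (second allele); ``-1`` marks a missing call and only ever
appears in raw, not-yet-preprocessed panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

#: default string alphabet for genotype files: hom-first, hom-second, het, missing
DEFAULT_CALLS = ("AA", "BB", "AB", "NA")


@dataclass
class GeneticMap:
    """Marker positions in centiMorgans on numbered chromosomes.

    Markers are stored sorted by (chromosome, position); construction
    re-sorts its inputs into that canonical order.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    _chrom_slices: list = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_cM = np.asarray(self.position_cM, dtype=np.float64)
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position_cM)):
            raise ValueError("marker_id, chromosome and position_cM must have equal length")
        if len(self.position_cM) and np.any(self.position_cM < 0):
            raise ValueError("map positions must be non-negative")
        order = np.lexsort((self.position_cM, self.chromosome))
        if not np.array_equal(order, np.arange(len(order))):
            self.marker_id = self.marker_id[order]
            self.chromosome = self.chromosome[order]
            self.position_cM = self.position_cM[order]
        self._chrom_slices = None

    @property
    def n_loci(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slices(self) -> list[tuple[int, slice, np.ndarray]]:
        """Per-chromosome ``(chromosome, slice, positions)`` in map order."""
        if self._chrom_slices is None:
            out = []
            for c in self.chromosomes:
                idx = np.flatnonzero(self.chromosome == c)
                sl = slice(idx[0], idx[-1] + 1)
                out.append((int(c), sl, self.position_cM[sl]))
            self._chrom_slices = out
        return self._chrom_slices

    def chrom_lengths(self) -> dict[int, float]:
        """Chromosome spans (max − min position) in cM."""
        return {c: float(pos[-1] - pos[0]) if len(pos) else 0.0
                for c, _, pos in self.chrom_slices()}

    def total_length(self) -> float:
        return float(sum(self.chrom_lengths().values()))

    def has_duplicate_positions(self) -> bool:
        for _, _, pos in self.chrom_slices():
            if len(pos) > 1 and np.any(np.diff(pos) == 0):
                return True
        return False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "chromosome": self.chromosome,
             "cM": self.position_cM}
        )


@dataclass
class FounderPanel:
    """Phased genotypes, program labels and genetic map for the base lines.

    ``haplotypes`` has shape ``(n_lines, 2, n_loci)`` with entries in
    {0, 1, MISSING}.  A clean (preprocessed or generated) panel is fully
    homozygous with no missing calls.
    """

    line_ids: np.ndarray
    program: np.ndarray
    haplotypes: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.program = np.asarray(self.program, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 + 1 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_lines, 2, n_loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise ValueError("number of loci differs between haplotypes and map")
        if len(self.line_ids) != self.haplotypes.shape[0]:
            raise ValueError("line_ids length does not match haplotypes")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")

    @property
    def n_lines(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def has_missing(self) -> bool:
        return bool((self.haplotypes == MISSING).any())

    def is_homozygous(self) -> bool:
        ok = self.haplotypes != MISSING
        both = ok.all(axis=1)
        return bool((self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :])[both].all())

    def dosage(self) -> np.ndarray:
        """Count of the second allele per line × locus (0, 1 or 2)."""
        if self.has_missing():
            raise ValueError("panel contains missing calls; preprocess first")
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def z_matrix(self) -> np.ndarray:
        """Marker coding for prediction: 1 hom-first, 0 het, −1 hom-second."""
        return (1 - self.dosage()).astype(np.int8)

    def allele2_frequency(self) -> np.ndarray:
        return self.dosage().mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# MAF spectra


def beta_maf(a: float = 0.5, b: float = 0.5,
             low: float | None = None, high: float = 0.5) -> Callable:
    """Truncated Beta(a, b) minor-allele-frequency sampler on (low, high].

    Beta(0.5, 0.5) gives the U-shaped spectrum typical of a breeding panel:
    many rare and many common variants.  When ``low`` is None the generator
    truncates at the panel's frequency resolution (one carrier line), the
    smallest MAF a segregating variant can have among n inbred lines.
    """
    dist = stats.beta(a, b)

    def draw(rng: np.random.Generator, size: int,
             resolution: float = 0.01) -> np.ndarray:
        lo = dist.cdf(resolution if low is None else low)
        hi = dist.cdf(high)
        return dist.ppf(lo + rng.random(size) * (hi - lo))

    return draw


def uniform_maf(low: float = 0.05, high: float = 0.5) -> Callable:
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size)

    return draw


# ---------------------------------------------------------------------------
# Synthetic generation


def _make_map(n_loci: int, n_chromosomes: int, total_map_cM: float,
              rng: np.random.Generator) -> GeneticMap:
    # loci split near-evenly; chromosome spans equal shares of the total map,
    # with first/last markers pinned to the chromosome ends so the realized
    # total map length equals total_map_cM exactly
    base, extra = divmod(n_loci, n_chromosomes)
    sizes = [base + (1 if i < extra else 0) for i in range(n_chromosomes)]
    chrom_len = total_map_cM / n_chromosomes
    ids, chroms, poss = [], [], []
    for c, size in enumerate(sizes, start=1):
        if size == 0:
            continue
        if size == 1:
            pos = np.array([rng.uniform(0, chrom_len)])
        else:
            interior = rng.uniform(0, chrom_len, size - 2)
            pos = np.sort(np.concatenate([[0.0, chrom_len], interior]))
            # continuous draws almost surely distinct; nudge ties if any
            while np.any(np.diff(pos) == 0):
                dup = np.flatnonzero(np.diff(pos) == 0) + 1
                pos[dup] += rng.uniform(0, chrom_len * 1e-9, len(dup))
                pos = np.sort(pos)
        order = np.arange(size)
        ids.extend(f"c{c}m{j:04d}" for j in order)
        chroms.extend([c] * size)
        poss.extend(pos)
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss))


def _ld_scores(gmap: GeneticMap, n_pool: int, corr_length_cM: float,
               locus_noise: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated scores used to place alleles on pool haplotypes.

    One Ornstein–Uhlenbeck (AR-1 in map distance) score track per ancestral
    haplotype, correlation exp(−d/corr_length_cM) between loci d cM apart,
    blended with locus-independent noise of weight ``locus_noise``.  Ranking
    haplotypes by these scores per locus yields allele placements whose
    between-locus correlation — hence the pool's linkage disequilibrium —
    decays smoothly with map distance.
    """
    z = np.empty((n_pool, gmap.n_loci))
    for _, sl, pos in gmap.chrom_slices():
        k = len(pos)
        eps = rng.standard_normal((n_pool, k))
        s = np.empty((n_pool, k))
        s[:, 0] = eps[:, 0]
        rho = np.exp(-np.diff(pos) / corr_length_cM)
        for i in range(1, k):
            s[:, i] = rho[i - 1] * s[:, i - 1] + np.sqrt(1 - rho[i - 1] ** 2) * eps[:, i]
        z[:, sl] = s
    w = locus_noise
    return np.sqrt(1 - w) * z + np.sqrt(w) * rng.standard_normal(z.shape)


def _mosaic_indices(gmap: GeneticMap, n_pool: int, depth: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Pool-haplotype index per locus for one mosaic line."""
    idx = np.empty(gmap.n_loci, dtype=np.int32)
    for _, sl, pos in gmap.chrom_slices():
        span = pos[-1] - pos[0] if len(pos) > 1 else 0.0
        n_sw = rng.poisson(span / 100.0 * depth)
        cuts = np.sort(rng.uniform(pos[0], pos[-1], n_sw)) if n_sw else np.empty(0)
        donors = rng.integers(0, n_pool, n_sw + 1)
        seg = np.searchsorted(cuts, pos, side="right")
        idx[sl] = donors[seg]
    return idx


def generate_founder_panel(
    n_lines: int = 764,
    n_loci: int = 1590,
    n_chromosomes: int = 7,
    total_map_cM: float = 1137.0,
    maf_spectrum: Callable | None = None,
    n_subpops: int = 2,
    divergence: float = 0.1,
    seed: int | np.random.Generator | None = None,
    n_ancestral_haplotypes: int = 20,
    mosaic_generations: float = 5.0,
    ld_decay_cM: float = 15.0,
    ld_locus_noise: float = 0.05,
    subpop_labels: Sequence[str] | None = None,
) -> FounderPanel:
    """Generate a synthetic panel of fully inbred lines with realistic LD.

    Each subpopulation (breeding program) descends from a small pool of
    ancestral haplotypes (default 20) drawn at Balding–Nichols-perturbed
    allele frequencies; every line is a recombination mosaic over its
    program's pool, so nearby loci are in strong linkage disequilibrium.
    Lines are fully homozygous (inbred).  Every locus is guaranteed
    polymorphic across the panel, mirroring a segregating SNP array.

    Parameters
    ----------
    maf_spectrum : callable(rng, size) -> array, optional
        Minor-allele-frequency sampler on (0, 0.5]; default is
        Beta(0.5, 0.5) truncated to (0.01, 0.5].
    divergence : float in [0, 1]
        Balding–Nichols F between subpopulation allele frequencies.
    mosaic_generations : float
        Recombination depth of the mosaic: expected switches per chromosome
        are span_cM / 100 × this value.
    ld_decay_cM : float
        Correlation length of the ancestral pool's allele-placement score
        field; sets how fast marker–marker LD decays with map distance.
    ld_locus_noise : float in [0, 1)
        Locus-independent score noise; caps the maximum short-range LD.
    """
    if n_lines < 1 or n_loci < 1 or n_chromosomes < 1:
        raise ValueError("panel dimensions must be positive")
    if total_map_cM <= 0:
        raise ValueError("total_map_cM must be positive")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if n_subpops < 1:
        raise ValueError("n_subpops must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if maf_spectrum is None:
        maf_spectrum = beta_maf()
    if subpop_labels is None:
        subpop_labels = [f"P{i + 1}" for i in range(n_subpops)]
    if len(subpop_labels) != n_subpops:
        raise ValueError("need one label per subpopulation")

    gmap = _make_map(n_loci, n_chromosomes, total_map_cM, rng)

    try:  # the default spectrum truncates at the panel's frequency resolution
        maf = maf_spectrum(rng, n_loci, resolution=1.0 / n_lines)
    except TypeError:
        maf = maf_spectrum(rng, n_loci)
    maf = np.clip(np.asarray(maf, dtype=float), 1e-9, 0.5)
    # arrange the drawn frequencies along the map by rank-matching them to a
    # spatially autocorrelated field: marginally the spectrum is untouched,
    # but neighboring loci get similar frequencies, as they do on real
    # haplotype structure (a prerequisite for appreciable pairwise LD)
    u = _ld_scores(gmap, 1, ld_decay_cM, ld_locus_noise, rng)[0]
    maf = np.sort(maf)[u.argsort().argsort()]
    # attach the minor allele to either label at random
    p = np.where(rng.random(n_loci) < 0.5, maf, 1.0 - maf)

    # subpopulation frequencies: Balding–Nichols with F = divergence; the
    # per-locus deviates are spatially correlated (programs diverge by
    # haplotype blocks, not locus by locus), via a Gaussian copula over the
    # same autocorrelated field used for LD
    sub_p = np.empty((n_subpops, n_loci))
    F = divergence
    for s in range(n_subpops):
        if F <= 0:
            sub_p[s] = p
        elif F >= 1:
            sub_p[s] = (rng.random(n_loci) < p).astype(float)
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            z = _ld_scores(gmap, 1, ld_decay_cM, ld_locus_noise, rng)[0]
            sub_p[s] = stats.beta.ppf(stats.norm.cdf(z), a, b)
    base, extra = divmod(n_lines, n_subpops)
    counts = [base + (1 if i < extra else 0) for i in range(n_subpops)]
    if 0 < F < 1:
        # recenter so the panel-wide frequency equals the spectrum draw
        # exactly: divergence redistributes an allele between programs
        # without distorting the marginal spectrum
        weights = np.asarray(counts, dtype=float) / n_lines
        sub_p += p - weights @ sub_p
        np.clip(sub_p, 0.0, 1.0, out=sub_p)

    def _stochastic_round(x):
        base = np.floor(x)
        return (base + (rng.random(x.shape) < x - base)).astype(np.int64)

    # ancestral pools: per locus, exactly round(pool × p_s) second alleles,
    # placed on the haplotypes ranked highest by a spatially autocorrelated
    # score field — pool frequencies track the target spectrum while nearby
    # loci share carriers, building linkage disequilibrium that decays with
    # map distance
    pools = []
    for s in range(n_subpops):
        k = _stochastic_round(n_ancestral_haplotypes * sub_p[s])
        z = _ld_scores(gmap, n_ancestral_haplotypes, ld_decay_cM,
                       ld_locus_noise, rng)
        order = np.argsort(-z, axis=0, kind="stable")
        rank = np.empty_like(order)
        cols = np.arange(n_loci)
        rank[order, cols] = np.arange(n_ancestral_haplotypes)[:, None]
        pools.append((rank < k).astype(np.int8))

    # line assembly: mosaic over the program's pool, fully homozygous
    geno = np.empty((n_lines, n_loci), dtype=np.int8)
    program = np.empty(n_lines, dtype=object)
    line_ids = np.empty(n_lines, dtype=object)
    row = 0
    sub_rows = []
    for s, cnt in enumerate(counts):
        sub_rows.append(np.arange(row, row + cnt))
        for j in range(cnt):
            idx = _mosaic_indices(gmap, n_ancestral_haplotypes,
                                  mosaic_generations, rng)
            geno[row] = pools[s][idx, np.arange(n_loci)]
            program[row] = subpop_labels[s]
            line_ids[row] = f"{subpop_labels[s]}_{j:04d}"
            row += 1

    # calibrate realized frequencies to the target spectrum: per subpopulation
    # and locus, flip the fewest random lines needed to hit the target carrier
    # count (removals keep the carriers' shared mosaic background; additions
    # are what realizes variants rarer than the ancestral-pool resolution)
    if n_lines >= 2:
        targets = np.vstack([_stochastic_round(len(sub_rows[s]) * sub_p[s])
                             for s in range(n_subpops)])
        total = targets.sum(axis=0)
        for locus in np.flatnonzero(total == 0):
            targets[rng.integers(n_subpops), locus] = 1
        for locus in np.flatnonzero(total == n_lines):
            s = int(rng.integers(n_subpops))
            if targets[s, locus] > 0:
                targets[s, locus] -= 1
            else:
                targets[1 - s if n_subpops == 2 else 0, locus] -= 1
        for s in range(n_subpops):
            rows_s = sub_rows[s]
            block = geno[rows_s, :]
            have = block.sum(axis=0)
            for locus in np.flatnonzero(have != targets[s]):
                want = int(targets[s, locus])
                carriers = rows_s[block[:, locus] == 1]
                if len(carriers) > want:
                    drop = rng.choice(carriers, len(carriers) - want,
                                      replace=False)
                    geno[drop, locus] = 0
                else:
                    absent = rows_s[block[:, locus] == 0]
                    add = rng.choice(absent, want - len(carriers),
                                     replace=False)
                    geno[add, locus] = 1

    haps = np.repeat(geno[:, None, :], 2, axis=1)
    return FounderPanel(line_ids, program, haps, gmap)


# ---------------------------------------------------------------------------
# Preprocessing


def _genotype_codes(haplotypes: np.ndarray) -> np.ndarray:
    """Per-call code: 0 hom-first, 1 het, 2 hom-second, −9 missing."""
    h = haplotypes
    miss = (h == MISSING).any(axis=1)
    code = h.sum(axis=1).astype(np.int16)
    code[miss] = -9
    return code


def preprocess_panel(
    raw_panel: FounderPanel,
    max_missing_marker: float = 0.10,
    max_missing_line: float = 0.10,
    forced_offset_cM: float = 0.01,
) -> FounderPanel:
    """Clean a raw genotype panel the way SNP-array breeding data are cleaned.

    In order: drop markers with a missing fraction above ``max_missing_marker``
    and then lines above ``max_missing_line``; collapse redundant markers
    (identical map position and identical calls) to one; force a
    ``forced_offset_cM`` interval between co-located markers with differing
    calls; set heterozygous calls to missing; impute remaining missing calls
    with the across-line modal genotype (ties broken toward the first allele).
    """
    if not 0 <= max_missing_marker <= 1 or not 0 <= max_missing_line <= 1:
        raise ValueError("missingness thresholds must lie in [0, 1]")
    if forced_offset_cM < 0:
        raise ValueError("forced_offset_cM must be non-negative")

    haps = raw_panel.haplotypes.copy()
    gmap = raw_panel.gmap
    code = _genotype_codes(haps)  # n_lines × n_loci
    missing = code == -9

    keep_m = missing.mean(axis=0) <= max_missing_marker
    haps = haps[:, :, keep_m]
    code = code[:, keep_m]
    marker_id = gmap.marker_id[keep_m]
    chrom = gmap.chromosome[keep_m]
    pos = gmap.position_cM[keep_m].copy()

    keep_l = (code == -9).mean(axis=1) <= max_missing_line
    haps = haps[keep_l]
    code = code[keep_l]
    line_ids = raw_panel.line_ids[keep_l]
    program = raw_panel.program[keep_l]

    # redundancy / forced offsets at shared map positions
    keep = np.ones(len(marker_id), dtype=bool)
    i = 0
    while i < len(marker_id):
        j = i + 1
        kept_cols = [i]
        while j < len(marker_id) and chrom[j] == chrom[i] and pos[j] == pos[i]:
            dup = any(np.array_equal(code[:, j], code[:, k]) for k in kept_cols)
            if dup:
                keep[j] = False
            else:
                pos[j] = pos[i] + forced_offset_cM * len(kept_cols)
                kept_cols.append(j)
            j += 1
        i = j
    haps = haps[:, :, keep]
    code = code[:, keep]
    marker_id, chrom, pos = marker_id[keep], chrom[keep], pos[keep]

    # heterozygotes -> missing, then modal imputation
    het = code == 1
    haps[np.repeat(het[:, None, :], 2, axis=1)] = MISSING
    code[het] = -9
    for m in range(code.shape[1]):
        miss_rows = code[:, m] == -9
        if not miss_rows.any():
            continue
        obs = code[~miss_rows, m]
        if len(obs) == 0:
            raise ValueError(
                f"marker {marker_id[m]!r} has no observed homozygous calls; "
                "mode imputation is undefined"
            )
        n2 = int((obs == 2).sum())
        fill = 1 if n2 > len(obs) - n2 else 0  # tie -> first allele
        haps[miss_rows, :, m] = fill
        code[miss_rows, m] = 2 * fill

    new_map = GeneticMap(marker_id, chrom, pos)
    # GeneticMap re-sorts; mirror that order in the genotype columns
    order = np.lexsort((pos, chrom))
    haps = haps[:, :, order]
    return FounderPanel(line_ids, program, haps, new_map)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _parse_calls(values: pd.DataFrame, calls=DEFAULT_CALLS) -> np.ndarray:
    hom1, hom2, het, na = calls
    n, m = values.shape
    haps = np.empty((n, 2, m), dtype=np.int8)
    numeric = values.dtypes.apply(
        lambda d: np.issubdtype(d, np.number)).all()
    if numeric:
        arr = values.to_numpy(dtype=float)
        lut = {1.0: (0, 0), -1.0: (1, 1), 0.0: (0, 1)}
        for (i, j), v in np.ndenumerate(arr):
            if np.isnan(v):
                haps[i, :, j] = MISSING
            elif v in lut:
                haps[i, :, j] = lut[v]
            else:
                raise ValueError(f"unparseable numeric call {v!r} "
                                 f"(line {values.index[i]!r}, marker {values.columns[j]!r})")
    else:
        lut = {hom1: (0, 0), hom2: (1, 1), het: (0, 1), na: (MISSING, MISSING)}
        arr = values.to_numpy(dtype=object)
        for (i, j), v in np.ndenumerate(arr):
            v = str(v)
            if v not in lut:
                raise ValueError(f"unparseable call {v!r} "
                                 f"(line {values.index[i]!r}, marker {values.columns[j]!r})")
            haps[i, :, j] = lut[v]
    return haps


def load_genotype_matrix(
    genotype_path,
    map_path,
    calls=DEFAULT_CALLS,
    preprocess: bool = True,
    **preprocess_kwargs,
) -> FounderPanel:
    """Read a lines × markers genotype table plus a genetic-map table.

    The genotype file is CSV/TSV with line ids in the first column and one
    column per marker; calls are either the string alphabet ``calls``
    (default AA/BB/AB/NA) or the numeric 1/−1/0/NaN dialect.  The map file
    needs columns ``marker_id``, ``chromosome``, ``cM``.  By default the
    loaded panel is passed through :func:`preprocess_panel`.
    """
    sep_g = "\t" if str(genotype_path).endswith((".tsv", ".txt")) else ","
    geno = pd.read_csv(genotype_path, sep=sep_g, index_col=0)
    if geno.index.has_duplicates:
        dups = geno.index[geno.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate line ids: {dups}")
    gmap_df = pd.read_csv(map_path)
    required = {"marker_id", "chromosome", "cM"}
    if not required.issubset(gmap_df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    gmap_df = gmap_df.set_index("marker_id")
    absent = [m for m in geno.columns if m not in gmap_df.index]
    if absent:
        raise ValueError(f"markers absent from the map: {absent}")
    gmap = GeneticMap(
        np.array(geno.columns, dtype=object),
        gmap_df.loc[geno.columns, "chromosome"].to_numpy(),
        gmap_df.loc[geno.columns, "cM"].to_numpy(dtype=float),
    )
    # order genotype columns to match the (sorted) map
    geno = geno.loc[:, list(gmap.marker_id)]
    haps = _parse_calls(geno, calls)
    panel = FounderPanel(
        np.array(geno.index, dtype=object),
        np.array(["pop"] * len(geno), dtype=object),
        haps,
        gmap,
    )
    if preprocess:
        panel = preprocess_panel(panel, **preprocess_kwargs)
    return panel


def write_genotype_matrix(panel: FounderPanel, genotype_path, map_path=None,
                          dialect: str = "calls", calls=DEFAULT_CALLS) -> None:
    """Export a panel as delimited text; round-trips bit-exactly."""
    code = _genotype_codes(panel.haplotypes)
    if dialect == "calls":
        hom1, hom2, het, na = calls
        lut = {0: hom1, 2: hom2, 1: het, -9: na}
        table = pd.DataFrame(
            [[lut[int(v)] for v in row] for row in code],
            index=panel.line_ids, columns=panel.gmap.marker_id,
        )
    elif dialect == "numeric":
        arr = np.where(code == -9, np.nan, 1.0 - code)
        table = pd.DataFrame(arr, index=panel.line_ids,
                             columns=panel.gmap.marker_id)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    table.to_csv(genotype_path)
    if map_path is not None:
        panel.gmap.to_frame().to_csv(map_path, index=False)
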