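"""Meiosis, crossing, and single-seed descent on a genetic map.

Gametes follow Mendelian segregation with a no-interference crossover
process: per chromosome the crossover count is Poisson(span_cM / 100) and
crossover positions are uniform over the marker span (the Haldane model).
There is no mutation, so every progeny allele exists in a parent.

An F3-derived line is represented by the genotype of a single F3 plant
(two selfing meioses below the F1), which may retain residual
heterozygosity — matching genotyping at the F3 stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FounderPanel, GeneticMap


@dataclass
class Individual:
    id: str
    haplotypes: np.ndarray  # (2, n_loci) int8 in {0, 1}
    cross_id: str = ""
    cycle: int = 0

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_loci)")

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int8)

    def is_homozygous(self) -> bool:
        return bool((self.haplotypes[0] == self.haplotypes[1]).all())


@dataclass
class Population:
    """A cohort of individuals sharing one locus set and map."""

    ids: np.ndarray
    haplotypes: np.ndarray  # (n, 2, n_loci) int8
    cross_ids: np.ndarray
    cycle: int = 0
    gmap: GeneticMap | None = field(default=None, repr=False)
    cross_parents: dict | None = field(default=None, repr=False)  # cross_id -> (p1, p2)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.cross_ids = np.asarray(self.cross_ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.cycle < 0:
            raise ValueError("cycle must be non-negative")
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[0] != len(self.ids):
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")

    def __len__(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def individual(self, i: int) -> Individual:
        return Individual(str(self.ids[i]), self.haplotypes[i],
                          str(self.cross_ids[i]), self.cycle)

    def dosage(self) -> np.ndarray:
        """Second-allele counts, shape (n, n_loci)."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def z_matrix(self) -> np.ndarray:
        """Marker coding 1/0/−1 (hom first / het / hom second)."""
        return (1 - self.dosage()).astype(np.int8)

    def subset(self, indices) -> "Population":
        idx = np.asarray(indices)
        return Population(self.ids[idx], self.haplotypes[idx],
                          self.cross_ids[idx], self.cycle, self.gmap,
                          self.cross_parents)

    @classmethod
    def from_panel(cls, panel: FounderPanel, cycle: int = 0) -> "Population":
        return cls(panel.line_ids.copy(), panel.haplotypes.copy(),
                   np.array([""] * panel.n_lines, dtype=object), cycle,
                   panel.gmap)

    def pedigree_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ids, "cross_id": self.cross_ids,
                            "cycle": self.cycle})
        if self.cross_parents:
            out["parent1"] = [self.cross_parents.get(c, ("", ""))[0]
                              for c in self.cross_ids]
            out["parent2"] = [self.cross_parents.get(c, ("", ""))[1]
                              for c in self.cross_ids]
        return out


def _gamete(hap_pair: np.ndarray, gmap: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, n_loci) haplotype pair."""
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for _, sl, pos in gmap.chrom_slices():
        span = pos[-1] - pos[0] if len(pos) > 1 else 0.0
        n_x = rng.poisson(span / 100.0) if span > 0 else 0
        start = int(rng.integers(2))
        if n_x == 0:
            out[sl] = hap_pair[start, sl]
            continue
        cuts = np.sort(rng.uniform(pos[0], pos[-1], n_x))
        source = (start + np.searchsorted(cuts, pos, side="right")) % 2
        seg = hap_pair[:, sl]
        out[sl] = np.where(source == 0, seg[0], seg[1])
    return out


def recombine_gamete(parent: Individual, gmap: GeneticMap,
                     rng: np.random.Generator) -> np.ndarray:
    """Public wrapper around the gamete sampler."""
    return _gamete(parent.haplotypes, gmap, rng)


def make_cross(parent1: Individual, parent2: Individual, gmap: GeneticMap,
               rng: np.random.Generator, id: str = "F1",
               cross_id: str = "", cycle: int = 0) -> Individual:
    """F1 from one recombinant gamete of each parent."""
    if parent1.haplotypes.shape != parent2.haplotypes.shape:
        raise ValueError("parents must share the locus set")
    haps = np.stack([_gamete(parent1.haplotypes, gmap, rng),
                     _gamete(parent2.haplotypes, gmap, rng)])
    return Individual(id, haps, cross_id, cycle)


def self_generation(plant: Individual, gmap: GeneticMap,
                    rng: np.random.Generator, id: str = "") -> Individual:
    """One self-fertilization: two independent gametes from the same plant."""
    haps = np.stack([_gamete(plant.haplotypes, gmap, rng),
                     _gamete(plant.haplotypes, gmap, rng)])
    return Individual(id or plant.id, haps, plant.cross_id, plant.cycle)


def ssd_to_f3(f1: Individual, gmap: GeneticMap,
              rng: np.random.Generator, id: str = "") -> Individual:
    """Single-seed descent F1 → F2 → F3; the F3 plant represents the line."""
    f2 = self_generation(f1, gmap, rng)
    f3 = self_generation(f2, gmap, rng, id=id)
    return f3


def develop_population(parents: Population, gmap: GeneticMap,
                       rng: np.random.Generator, n_crosses: int | None = None,
                       lines_per_cross: int = 20, pairing: str = "random",
                       programs: np.ndarray | None = None,
                       cycle: int = 1) -> Population:
    """Pair parents, cross each pair once, and derive F3 lines per cross.

    ``pairing="random"`` draws a uniformly random perfect matching on the
    parents; ``pairing="paired"`` mates across the two groups given by
    ``programs`` (program-vs-program crossing, used for cycle 1).  Every
    parent is used in exactly one cross.
    """
    n = len(parents)
    if n % 2:
        raise ValueError("parent count must be even")
    if n_crosses is None:
        n_crosses = n // 2
    if 2 * n_crosses != n:
        raise ValueError("number of parents must equal 2 × n_crosses")
    if pairing == "random":
        perm = rng.permutation(n)
        pairs = perm.reshape(n_crosses, 2)
    elif pairing == "paired":
        if programs is None:
            raise ValueError("paired mating requires program labels")
        programs = np.asarray(programs)
        groups = [np.flatnonzero(programs == g) for g in np.unique(programs)]
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("paired mating needs two equal-sized groups")
        a = rng.permutation(groups[0])
        b = rng.permutation(groups[1])
        pairs = np.stack([a, b], axis=1)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    n_lines = n_crosses * lines_per_cross
    haps = np.empty((n_lines, 2, parents.n_loci), dtype=np.int8)
    ids = np.empty(n_lines, dtype=object)
    cross_ids = np.empty(n_lines, dtype=object)
    row = 0
    cross_parents = {}
    for c, (i, j) in enumerate(pairs):
        cid = f"C{cycle}_X{c:03d}"
        cross_parents[cid] = (str(parents.ids[int(i)]),
                              str(parents.ids[int(j)]))
        f1 = make_cross(parents.individual(int(i)), parents.individual(int(j)),
                        gmap, rng, id=f"{cid}_F1", cross_id=cid, cycle=cycle)
        for k in range(lines_per_cross):
            line = ssd_to_f3(f1, gmap, rng, id=f"{cid}_{k:02d}")
            haps[row] = line.haplotypes
            ids[row] = line.id
            cross_ids[row] = cid
            row += 1
    return Population(ids, haps, cross_ids, cycle, gmap, cross_parents)
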