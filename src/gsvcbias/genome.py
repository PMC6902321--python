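"""Founder genomes and meiosis.

The historical phase is a discrete-generation Wright-Fisher population with
recurrent symmetric mutation and Poisson recombination: the crossover count
per chromosome is Poisson with mean equal to the map length in Morgans and
crossover positions are uniform along the chromosome (Haldane model, no
interference).  Mutation occurs only during this phase; all later meiosis is
drift + recombination only.  Running a few hundred generations from an
intermediate starting frequency produces the U-shaped allele-frequency
spectrum and the short-range LD the single-step analyses rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "GeneticMap",
    "HaplotypePopulation",
    "QtlEffectSet",
    "run_historical",
    "select_loci",
    "assign_qtl_effects",
    "drop_gamete",
    "make_gametes",
]


@dataclass(frozen=True)
class GeneticMap:
    """Positions (cM within chromosome) and kinds of all loci, chromosome-sorted."""

    chrom: np.ndarray  # int32 (L,)
    pos_cm: np.ndarray  # float64 (L,)
    is_qtl: np.ndarray  # bool (L,)
    chrom_length_cm: float
    n_chromosomes: int

    def __post_init__(self) -> None:
        if np.any(self.pos_cm < 0) or np.any(self.pos_cm > self.chrom_length_cm):
            raise ValueError("locus positions must lie within [0, chromosome length]")
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("loci must be sorted by chromosome")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chrom_bounds(self) -> np.ndarray:
        """Start offsets of each chromosome in the locus arrays (length n_chr+1)."""
        return np.searchsorted(self.chrom, np.arange(self.n_chromosomes + 1)).astype(np.int64)

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int,
        chrom_length_cm: float,
        markers_per_chrom: int,
        qtl_per_chrom: int,
    ) -> "GeneticMap":
        """Markers and QTL each uniformly spaced within every chromosome."""
        chroms, pos, qtl = [], [], []
        for c in range(n_chromosomes):
            pm = (np.arange(markers_per_chrom) + 0.5) * chrom_length_cm / markers_per_chrom
            pq = (np.arange(qtl_per_chrom) + 0.75) * chrom_length_cm / max(qtl_per_chrom, 1)
            p = np.concatenate([pm, pq])
            k = np.concatenate([np.zeros(pm.size, bool), np.ones(pq.size, bool)])
            order = np.argsort(p, kind="stable")
            chroms.append(np.full(p.size, c, np.int32))
            pos.append(p[order])
            qtl.append(k[order])
        return cls(
            chrom=np.concatenate(chroms),
            pos_cm=np.concatenate(pos),
            is_qtl=np.concatenate(qtl),
            chrom_length_cm=float(chrom_length_cm),
            n_chromosomes=n_chromosomes,
        )

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        idx = np.sort(np.asarray(idx))
        return GeneticMap(
            chrom=self.chrom[idx],
            pos_cm=self.pos_cm[idx],
            is_qtl=self.is_qtl[idx],
            chrom_length_cm=self.chrom_length_cm,
            n_chromosomes=self.n_chromosomes,
        )


@dataclass
class HaplotypePopulation:
    """Phased biallelic haplotypes (n, 2, L) with their genetic map."""

    haplo: np.ndarray  # uint8 (n, 2, L)
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.haplo.ndim != 3 or self.haplo.shape[1] != 2:
            raise ValueError("haplo must have shape (n_individuals, 2, n_loci)")
        if self.haplo.shape[2] != self.gmap.n_loci:
            raise ValueError("haplotype locus count does not match map")

    @property
    def n_individuals(self) -> int:
        return self.haplo.shape[0]

    def genotypes(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 counts in {0,1,2}, optionally restricted to given loci."""
        g = self.haplo.sum(axis=1, dtype=np.int16)
        return g if loci is None else g[:, loci]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplo.mean(axis=(0, 1))

    def segregating(self) -> np.ndarray:
        p = self.allele_frequencies()
        return (p > 0.0) & (p < 1.0)


@dataclass(frozen=True)
class QtlEffectSet:
    """Additive allele-substitution effects on the map's QTL loci.

    Effects are drawn standard-normal and rescaled by a single constant so
    that the empirical variance of the founder true breeding values equals
    ``target_base_variance`` exactly, which makes the founder-population
    truth a configured quantity rather than a random one.
    """

    qtl_idx: np.ndarray  # indices into the map's locus arrays
    effects: np.ndarray  # per-QTL effect, trait units per allele copy
    target_base_variance: float

    def breeding_values(self, pop_or_haplo) -> np.ndarray:
        haplo = pop_or_haplo.haplo if isinstance(pop_or_haplo, HaplotypePopulation) else pop_or_haplo
        geno = haplo[:, 0, :][:, self.qtl_idx].astype(np.float64) + haplo[:, 1, :][:, self.qtl_idx]
        return geno @ self.effects


# ---------------------------------------------------------------------------
# meiosis kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _meiosis_kernel(haplo, parent, cstart, pos_m, clen_m, mut_rate, seed, out):  # pragma: no cover
    np.random.seed(seed)
    n_gam = parent.shape[0]
    n_chr = cstart.shape[0] - 1
    n_loci = pos_m.shape[0]
    for g in range(n_gam):
        p = parent[g]
        for c in range(n_chr):
            lo, hi = cstart[c], cstart[c + 1]
            k = np.random.poisson(clen_m)
            xo = np.sort(np.random.uniform(0.0, clen_m, k))
            phase = np.random.randint(0, 2)
            xi = 0
            for l in range(lo, hi):
                while xi < k and xo[xi] < pos_m[l]:
                    phase = 1 - phase
                    xi += 1
                out[g, l] = haplo[p, phase, l]
        if mut_rate > 0.0:
            nm = np.random.poisson(mut_rate * n_loci)
            for _ in range(nm):
                l = np.random.randint(0, n_loci)
                out[g, l] = 1 - out[g, l]


def make_gametes(
    haplo: np.ndarray,
    parents: np.ndarray,
    gmap: GeneticMap,
    seed: int,
    mutation_rate: float = 0.0,
) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` (indices into ``haplo``)."""
    parents = np.asarray(parents, np.int64)
    out = np.empty((parents.size, gmap.n_loci), np.uint8)
    _meiosis_kernel(
        haplo,
        parents,
        gmap.chrom_bounds(),
        gmap.pos_cm / 100.0,
        gmap.chrom_length_cm / 100.0,
        float(mutation_rate),
        np.uint32(seed) & np.uint32(0x7FFFFFFF),
        out,
    )
    return out


def drop_gamete(parent_haplos: np.ndarray, gmap: GeneticMap, seed: int) -> np.ndarray:
    """Single gamete from one parent's two phased haplotypes (2, L)."""
    if parent_haplos.shape != (2, gmap.n_loci):
        raise ValueError("parent_haplos must have shape (2, n_loci)")
    return make_gametes(parent_haplos[None, :, :], np.zeros(1, np.int64), gmap, seed)[0]


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------

def run_historical(genome, historical, seed: int) -> HaplotypePopulation:
    """Wright-Fisher burn-in; returns the final generation's haplotypes.

    Parameters mirror :class:`~gsvcbias.config.GenomeConfig` /
    :class:`~gsvcbias.config.HistoricalConfig`.
    """
    if historical.pop_size <= 0:
        raise ValueError("historical population size must be positive")
    gmap = GeneticMap.uniform(
        genome.n_chromosomes,
        genome.chrom_length_cm,
        genome.markers_per_chrom,
        genome.qtl_per_chrom,
    )
    if gmap.n_loci == 0:
        raise ValueError("genome has zero loci")
    rng = np.random.default_rng(seed)
    n = historical.pop_size
    haplo = (rng.random((n, 2, gmap.n_loci)) < historical.initial_frequency).astype(np.uint8)
    for _ in range(historical.n_generations):
        sires = rng.integers(0, n, n)
        dams = (sires + 1 + rng.integers(0, n - 1, n)) % n  # distinct second parent
        parents = np.concatenate([sires, dams])
        kid_seed = int(rng.integers(0, 2**31 - 1))
        gam = make_gametes(haplo, parents, gmap, kid_seed, historical.mutation_rate)
        haplo = np.stack([gam[:n], gam[n:]], axis=1)
    return HaplotypePopulation(haplo=haplo, gmap=gmap)


def select_loci(
    pop: HaplotypePopulation, n_markers: int, n_qtl: int, seed: int
) -> HaplotypePopulation:
    """Restrict to a random panel of segregating markers and QTL."""
    seg = pop.segregating()
    markers = np.flatnonzero(seg & ~pop.gmap.is_qtl)
    qtls = np.flatnonzero(seg & pop.gmap.is_qtl)
    if markers.size < n_markers:
        raise ValueError(
            f"requested {n_markers} markers but only {markers.size} segregate"
        )
    if qtls.size < n_qtl:
        raise ValueError(f"requested {n_qtl} QTL but only {qtls.size} segregate")
    rng = np.random.default_rng(seed)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(markers, n_markers, replace=False),
                rng.choice(qtls, n_qtl, replace=False),
            ]
        )
    )
    return HaplotypePopulation(haplo=pop.haplo[:, :, keep].copy(), gmap=pop.gmap.subset(keep))


def assign_qtl_effects(
    pop: HaplotypePopulation, target_var: float, seed: int
) -> QtlEffectSet:
    """Standard-normal QTL effects rescaled so founder TBV variance == target."""
    qtl_idx = pop.gmap.qtl_idx
    if qtl_idx.size == 0:
        raise ValueError("population has no QTL loci")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(qtl_idx.size)
    geno = pop.genotypes(qtl_idx).astype(np.float64)
    tbv = geno @ raw
    v = tbv.var(ddof=1)
    if target_var == 0.0:
        return QtlEffectSet(qtl_idx=qtl_idx, effects=np.zeros_like(raw), target_base_variance=0.0)
    if v <= 0.0:
        raise ValueError("all QTL monomorphic: founder TBV variance cannot be scaled")
    return QtlEffectSet(
        qtl_idx=qtl_idx,
        effects=raw * np.sqrt(target_var / v),
        target_base_variance=float(target_var),
    )
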