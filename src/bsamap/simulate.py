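"""Forward simulation of an EMS mapping cross and pooled sequencing.

This module generates the world a bulked-segregant analysis assumes: an
inbred mutant line carrying exactly one recessive causal SNP among EMS
background mutations (with the EMS-typical G>A / C>T transition bias),
F1/F2/BC1 progeny under Mendelian inheritance with a Haldane
(Poisson-count, uniform-position, no-interference) crossover model,
phenotype-selected pools, and pooled read counts drawn at Poisson depth
with a symmetric base-miscall rate.

Coordinates are 1-based inclusive throughout. Alleles are coded 0
(reference) and 1 (alternate); parents are fully homozygous, so a parent
carries a single allele vector over the variant sites.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "VariantSite",
    "ParentLine",
    "F1Hybrid",
    "F2Individual",
    "Pool",
    "CoordinateError",
    "PoolCapacityError",
    "EmptyPoolError",
    "MUTANT",
    "WILDTYPE",
    "simulate_ems_line",
    "reference_line",
    "make_f1",
    "simulate_f2",
    "simulate_bc1",
    "select_pool",
    "simulate_pool_counts",
    "simulate_parent_counts",
    "causal_index",
    "COUNT_COLUMNS",
]

MUTANT = "mutant"
WILDTYPE = "wildtype"

#: canonical column order of a pool-counts table
COUNT_COLUMNS = ("chrom", "pos", "ref", "alt", "pool", "ref_count", "alt_count")

_BASES = ("A", "C", "G", "T")
# EMS alkylates guanine; the canonical product is a G:C -> A:T transition,
# seen as G>A on one strand and C>T on the other.
_EMS_PAIRS = (("G", "A"), ("C", "T"))
_NON_EMS_PAIRS = tuple(
    (r, a) for r in _BASES for a in _BASES if r != a and (r, a) not in _EMS_PAIRS
)


class CoordinateError(ValueError):
    """A genomic coordinate falls outside the genome."""


class PoolCapacityError(ValueError):
    """Fewer qualifying individuals than the requested pool size."""


class EmptyPoolError(ValueError):
    """Pooled sequencing of a pool with no members."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths and a genetic map.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    recombination_rate
        cM per Mb, either one global value or a per-chromosome mapping.
        Default 2.5 cM/Mb, a tomato-like order of magnitude.
    """

    chromosomes: tuple[tuple[str, int], ...]
    recombination_rate: float | Mapping[str, float] = 2.5

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def rate(self, chrom: str) -> float:
        if isinstance(self.recombination_rate, Mapping):
            return float(self.recombination_rate[chrom])
        return float(self.recombination_rate)

    def map_length_morgans(self, chrom: str) -> float:
        """Genetic length: (cM/Mb) * Mb / 100."""
        return self.rate(chrom) * self.length(chrom) / 1e6 / 100.0

    def contains(self, chrom: str, pos: int) -> bool:
        try:
            return 1 <= pos <= self.length(chrom)
        except KeyError:
            return False


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV: the atom of every BSA statistic."""

    chrom: str
    pos: int
    ref: str
    alt: str
    is_causal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        for b in (self.ref, self.alt):
            if b not in _BASES:
                raise ValueError(f"invalid base {b!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ParentLine:
    """A fully homozygous (inbred) parent.

    ``alleles[i]`` is 0 or 1: the single allele the line carries at
    ``sites[i]`` on both chromosomes.
    """

    name: str
    sites: list[VariantSite]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sites),):
            raise ValueError("alleles must align with sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 (ref) or 1 (alt)")


@dataclass
class F1Hybrid:
    """The heterozygous F1: one haplotype from each parent."""

    sites: list[VariantSite]
    hap_a: np.ndarray
    hap_b: np.ndarray


@dataclass
class F2Individual:
    """A diploid segregant with a recessive phenotype call."""

    hap1: np.ndarray
    hap2: np.ndarray
    phenotype: str

    def genotype(self, i: int) -> int:
        """Alternate-allele dosage (0, 1 or 2) at site index ``i``."""
        return int(self.hap1[i]) + int(self.hap2[i])

    @property
    def dosages(self) -> np.ndarray:
        return (self.hap1 + self.hap2).astype(np.int8)


@dataclass(frozen=True)
class Pool:
    """A phenotype-selected bulk: indices into its source population."""

    name: str
    phenotype_class: str
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def causal_index(sites: Sequence[VariantSite]) -> int:
    """Index of the unique causal site; raises if there is not exactly one."""
    idx = [i for i, s in enumerate(sites) if s.is_causal]
    if len(idx) != 1:
        raise ValueError(f"expected exactly one causal site, found {len(idx)}")
    return idx[0]


def _draw_substitution(rng: np.random.Generator, transition_fraction: float) -> tuple[str, str]:
    if rng.random() < transition_fraction:
        return _EMS_PAIRS[rng.integers(len(_EMS_PAIRS))]
    return _NON_EMS_PAIRS[rng.integers(len(_NON_EMS_PAIRS))]


def simulate_ems_line(
    genome: GenomeSpec,
    n_background: int,
    ems_transition_fraction: float = 0.9,
    causal_chrom_pos: tuple[str, int] = ("chr8", 47_106_679),
    seed: int | None = None,
    causal_ref: str = "T",
    causal_alt: str = "A",
    name: str = "mutant",
) -> tuple[list[VariantSite], ParentLine]:
    """Simulate an EMS-mutagenised inbred line.

    Returns ``n_background + 1`` variant sites at unique positions (position
    collisions are resampled, never dropped) and a parent line homozygous
    for the alternate allele at every one of them. Exactly one site — at
    ``causal_chrom_pos`` — is flagged causal. A fraction
    ``ems_transition_fraction`` of background substitutions are G>A or C>T,
    the EMS signature; the remainder are drawn uniformly from the other
    substitution classes. The causal substitution defaults to T>A (the
    mapped locus sits in a minus-strand gene, so the coding-strand change
    is A>T).
    """
    if not 0.0 <= ems_transition_fraction <= 1.0:
        raise ValueError("ems_transition_fraction must be in [0, 1]")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    c_chrom, c_pos = causal_chrom_pos
    if not genome.contains(c_chrom, c_pos):
        raise CoordinateError(
            f"causal position {c_chrom}:{c_pos} lies outside the genome"
        )

    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()

    taken = {(c_chrom, c_pos)}
    sites = [VariantSite(c_chrom, c_pos, causal_ref, causal_alt, is_causal=True)]
    while len(sites) < n_background + 1:
        ci = rng.choice(len(lengths), p=probs)
        chrom, length = genome.chromosomes[ci]
        pos = int(rng.integers(1, length + 1))
        if (chrom, pos) in taken:
            continue  # collision: resample
        taken.add((chrom, pos))
        ref, alt = _draw_substitution(rng, ems_transition_fraction)
        sites.append(VariantSite(chrom, pos, ref, alt))

    order = {n: i for i, n in enumerate(genome.names)}
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    line = ParentLine(name, sites, np.ones(len(sites), dtype=np.int8))
    return sites, line


def reference_line(name: str, sites: Sequence[VariantSite]) -> ParentLine:
    """A parent identical to the reference genome at every site."""
    return ParentLine(name, list(sites), np.zeros(len(sites), dtype=np.int8))


def make_f1(parent_a: ParentLine, parent_b: ParentLine) -> F1Hybrid:
    if [s.key for s in parent_a.sites] != [s.key for s in parent_b.sites]:
        raise ValueError("parents must share the same site table")
    return F1Hybrid(parent_a.sites, parent_a.alleles.copy(), parent_b.alleles.copy())


def _sites_by_chrom(
    sites: Sequence[VariantSite],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, tuple[list[int], list[int]]] = {}
    for i, s in enumerate(sites):
        by.setdefault(s.chrom, ([], []))[0].append(i)
        by[s.chrom][1].append(s.pos)
    return {
        c: (np.asarray(ix, dtype=np.intp), np.asarray(ps, dtype=float))
        for c, (ix, ps) in by.items()
    }


def _gamete(
    hyb: F1Hybrid,
    layout: dict[str, tuple[np.ndarray, np.ndarray]],
    genome: GenomeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: Poisson crossovers, uniform positions, random phase."""
    out = np.empty(len(hyb.sites), dtype=np.int8)
    for chrom, (idx, pos) in layout.items():
        start = int(rng.integers(2))
        k = int(rng.poisson(genome.map_length_morgans(chrom)))
        if k == 0:
            src = hyb.hap_a if start == 0 else hyb.hap_b
            out[idx] = src[idx]
        else:
            xo = np.sort(rng.uniform(0.0, genome.length(chrom), size=k))
            phase = (start + np.searchsorted(xo, pos)) % 2
            out[idx] = np.where(phase == 0, hyb.hap_a[idx], hyb.hap_b[idx])
    return out


def _phenotype(hap1: np.ndarray, hap2: np.ndarray, ci: int) -> str:
    return MUTANT if hap1[ci] == 1 and hap2[ci] == 1 else WILDTYPE


def simulate_f2(
    parent_a: ParentLine,
    parent_b: ParentLine,
    n: int,
    genome: GenomeSpec,
    seed: int | None = None,
) -> list[F2Individual]:
    """Self the F1 of ``parent_a`` x ``parent_b``: each F2 is two
    independent F1 gametes. Phenotype is recessive at the causal site."""
    if n < 1:
        raise ValueError("n must be >= 1")
    f1 = make_f1(parent_a, parent_b)
    rng = np.random.default_rng(seed)
    layout = _sites_by_chrom(f1.sites)
    ci = causal_index(f1.sites)
    out = []
    for _ in range(n):
        h1 = _gamete(f1, layout, genome, rng)
        h2 = _gamete(f1, layout, genome, rng)
        out.append(F2Individual(h1, h2, _phenotype(h1, h2, ci)))
    return out


def simulate_bc1(
    f1_parent: F1Hybrid,
    recurrent_parent: ParentLine,
    n: int,
    genome: GenomeSpec,
    seed: int | None = None,
) -> list[F2Individual]:
    """Backcross: one F1 gamete plus one (trivially homozygous) gamete from
    the recurrent parent. With the mutant line recurrent, phenotypes
    segregate 1:1; with the wild type recurrent, no mutants appear."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if [s.key for s in f1_parent.sites] != [s.key for s in recurrent_parent.sites]:
        raise ValueError("F1 and recurrent parent must share the same site table")
    rng = np.random.default_rng(seed)
    layout = _sites_by_chrom(f1_parent.sites)
    ci = causal_index(f1_parent.sites)
    out = []
    for _ in range(n):
        h1 = _gamete(f1_parent, layout, genome, rng)
        h2 = recurrent_parent.alleles.copy()
        out.append(F2Individual(h1, h2, _phenotype(h1, h2, ci)))
    return out


def select_pool(
    population: Sequence[F2Individual],
    phenotype_class: str,
    size: int,
    seed: int | None = None,
    name: str | None = None,
) -> Pool:
    """Uniform sample, without replacement, of ``size`` individuals of the
    requested phenotype class."""
    if size < 0:
        raise ValueError("size must be >= 0")
    qualifying = [i for i, ind in enumerate(population) if ind.phenotype == phenotype_class]
    if len(qualifying) < size:
        raise PoolCapacityError(
            f"requested {size} {phenotype_class!r} individuals but only "
            f"{len(qualifying)} qualify (short by {size - len(qualifying)})"
        )
    rng = np.random.default_rng(seed)
    members = tuple(sorted(rng.choice(qualifying, size=size, replace=False).tolist()))
    return Pool(name or f"{phenotype_class}_pool", phenotype_class, members)


def _counts_frame(
    sites: Sequence[VariantSite],
    pool_name: str,
    ref_count: np.ndarray,
    alt_count: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "pool": pool_name,
            "ref_count": ref_count.astype(np.int64),
            "alt_count": alt_count.astype(np.int64),
        }
    )


def _sample_counts(
    alt_freq: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
    fixed_depth: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = alt_freq.shape[0]
    if fixed_depth:
        depth = np.full(n, int(round(mean_depth)), dtype=np.int64)
    else:
        depth = rng.poisson(mean_depth, size=n)
    # each read draws a haplotype uniformly with replacement and reports its
    # allele, miscalled with probability error_rate -> Binomial(depth, p)
    p = alt_freq * (1.0 - error_rate) + (1.0 - alt_freq) * error_rate
    alt = rng.binomial(depth, p)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


def simulate_pool_counts(
    pool: Pool,
    population: Sequence[F2Individual],
    sites: Sequence[VariantSite],
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int | None = None,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """Pooled sequencing of a bulk.

    Per site, depth is Poisson(``mean_depth``) (or exactly ``mean_depth``
    with ``fixed_depth=True``); each read samples one of the pool's
    ``2 * size`` haplotypes uniformly and reports its allele, flipped
    ref<->alt with probability ``error_rate``. Returns a tidy table with
    columns :data:`COUNT_COLUMNS`; ``ref_count + alt_count`` is the depth.
    """
    if pool.size == 0:
        raise EmptyPoolError(f"pool {pool.name!r} has no members")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    dosage = np.zeros(len(sites), dtype=np.int64)
    for i in pool.members:
        ind = population[i]
        dosage += ind.hap1.astype(np.int64) + ind.hap2.astype(np.int64)
    alt_freq = dosage / (2.0 * pool.size)
    ref_c, alt_c = _sample_counts(alt_freq, mean_depth, error_rate, rng, fixed_depth)
    return _counts_frame(sites, pool.name, ref_c, alt_c)


def simulate_parent_counts(
    parent: ParentLine,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int | None = None,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """Whole-genome resequencing of an inbred parent (a 'pool' of one)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    alt_freq = parent.alleles.astype(float)
    ref_c, alt_c = _sample_counts(alt_freq, mean_depth, error_rate, rng, fixed_depth)
    return _counts_frame(parent.sites, parent.name, ref_c, alt_c)
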