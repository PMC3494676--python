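"""Populations, pedigrees and pedigree-based coancestry.

A :class:`Population` is a cohort of ``N`` individuals (exactly ``N/2``
males and ``N/2`` females) stored as stacked genotype arrays for speed;
:meth:`Population.individual` materializes a conventional per-individual
view.  The :class:`Pedigree` records (id, sire, dam, generation) for every
individual since generation 0 and maintains the additive-relationship
recursion incrementally, so kinship lookups during management are O(1)
slices.

Coancestry follows the standard tabular method: founders are unrelated and
non-inbred, ``f(i,i) = (1 + F_i)/2``, and for non-founders
``f(i,j) = [f(sire_i, j) + f(dam_i, j)] / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneticMap, Genome, Haplotype, build_founder_genome, sample_gametes_array
from .markers import MarkerPanel

__all__ = [
    "Individual",
    "Population",
    "Pedigree",
    "found_population",
    "admix_generation",
    "breed",
    "coancestry_matrix",
]


@dataclass(frozen=True)
class Individual:
    id: int
    sex: str  # "M" or "F"
    sire_id: int | None
    dam_id: int | None
    generation: int
    genome: Genome


class Pedigree:
    """Append-only pedigree with an incrementally maintained kinship matrix."""

    def __init__(self) -> None:
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.generation = np.empty(0, dtype=np.int64)
        self._K = np.empty((0, 0))

    @property
    def n(self) -> int:
        return self.sire.size

    def add_founders(self, n: int) -> np.ndarray:
        """Register ``n`` unrelated, non-inbred founders; returns their ids."""
        if self.n:
            raise ValueError("founders must be added before any offspring")
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        self.generation = np.zeros(n, dtype=np.int64)
        self._K = np.eye(n) * 0.5
        return np.arange(n)

    def add_offspring(self, sires: np.ndarray, dams: np.ndarray, generation: int) -> np.ndarray:
        """Register offspring of recorded parents; returns the new ids.

        Extends the kinship matrix by the tabular recursion, vectorized
        over the new cohort.
        """
        sires = np.asarray(sires, dtype=np.int64)
        dams = np.asarray(dams, dtype=np.int64)
        if sires.max(initial=-1) >= self.n or dams.max(initial=-1) >= self.n:
            raise KeyError("parent id not in pedigree")
        n_old, n_new = self.n, sires.size
        ids = np.arange(n_old, n_old + n_new)
        self.sire = np.concatenate([self.sire, sires])
        self.dam = np.concatenate([self.dam, dams])
        self.generation = np.concatenate(
            [self.generation, np.full(n_new, generation, dtype=np.int64)]
        )
        K = np.empty((n_old + n_new, n_old + n_new))
        K[:n_old, :n_old] = self._K
        # new x old: f(i,j) = [f(s_i,j) + f(d_i,j)] / 2
        new_old = 0.5 * (self._K[sires, :] + self._K[dams, :])
        K[n_old:, :n_old] = new_old
        K[:n_old, n_old:] = new_old.T
        # new x new (i != j): quarter-sum over the two parent pairs
        Kp = self._K
        new_new = 0.25 * (
            Kp[np.ix_(sires, sires)]
            + Kp[np.ix_(sires, dams)]
            + Kp[np.ix_(dams, sires)]
            + Kp[np.ix_(dams, dams)]
        )
        diag = 0.5 * (1.0 + Kp[sires, dams])
        new_new[np.diag_indices(n_new)] = diag
        K[n_old:, n_old:] = new_new
        self._K = K
        return ids

    def kinship(self, ids_a: np.ndarray, ids_b: np.ndarray | None = None) -> np.ndarray:
        """Pairwise coancestry matrix between two id lists."""
        a = np.asarray(ids_a, dtype=np.int64)
        b = a if ids_b is None else np.asarray(ids_b, dtype=np.int64)
        return self._K[np.ix_(a, b)]

    def inbreeding(self, ids: np.ndarray) -> np.ndarray:
        """F_i = 2 f(i,i) - 1."""
        ids = np.asarray(ids, dtype=np.int64)
        return 2.0 * self._K[ids, ids] - 1.0

    def members_of(self, generation: int) -> np.ndarray:
        return np.nonzero(self.generation == generation)[0]

    def export(self) -> np.ndarray:
        """3-column (id, sire, dam) table; -1 marks unknown parents."""
        return np.column_stack([np.arange(self.n), self.sire, self.dam])


def coancestry_matrix(ped: Pedigree, members: np.ndarray) -> np.ndarray:
    """Symmetric coancestry matrix for ``members`` under the tabular method."""
    return ped.kinship(members)


@dataclass
class Population:
    """One discrete generation of N individuals with stacked genotypes.

    ``nonmarker`` is ``(N, 2, L)`` int32 of founder allele IDs; ``marker``
    is ``(N, 2, M)`` int8 of marker allele indices.  ``origin_native`` maps
    founder index -> True when that founder was native, which makes the
    origin of any allele ID ``a`` recoverable as ``origin_native[a // 2]``.
    """

    generation: int
    ids: np.ndarray
    is_male: np.ndarray
    nonmarker: np.ndarray
    marker: np.ndarray
    origin_native: np.ndarray

    @property
    def size(self) -> int:
        return self.ids.size

    def males(self) -> np.ndarray:
        return np.nonzero(self.is_male)[0]

    def females(self) -> np.ndarray:
        return np.nonzero(~self.is_male)[0]

    def individual(self, i: int, ped: Pedigree | None = None) -> Individual:
        g = Genome(
            Haplotype(self.nonmarker[i, 0], self.marker[i, 0]),
            Haplotype(self.nonmarker[i, 1], self.marker[i, 1]),
        )
        sire = dam = None
        if ped is not None and ped.sire[self.ids[i]] >= 0:
            sire = int(ped.sire[self.ids[i]])
            dam = int(ped.dam[self.ids[i]])
        return Individual(
            id=int(self.ids[i]),
            sex="M" if self.is_male[i] else "F",
            sire_id=sire,
            dam_id=dam,
            generation=self.generation,
            genome=g,
        )


def _assign_founder_sexes(N: int, n_exogenous: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(1/2) sexes for exogenous founders, natives fill the quota.

    Returns a boolean is_male array whose first ``n_exogenous`` entries are
    the exogenous founders.  Redraws in the (rare) event that one sex's
    exogenous count alone exceeds N/2.
    """
    half = N // 2
    for _ in range(1000):
        exo_male = rng.random(n_exogenous) < 0.5
        m_exo = int(exo_male.sum())
        if m_exo <= half and (n_exogenous - m_exo) <= half:
            break
    else:  # pragma: no cover - unreachable for n_exogenous <= N
        raise RuntimeError("infeasible sex quota")
    is_male = np.empty(N, dtype=bool)
    is_male[:n_exogenous] = exo_male
    n_native_male = half - m_exo
    native = np.zeros(N - n_exogenous, dtype=bool)
    native[:n_native_male] = True
    rng.shuffle(native)
    is_male[n_exogenous:] = native
    return is_male


def found_population(
    N: int,
    n_exogenous: int,
    panel: MarkerPanel,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[Population, Pedigree]:
    """Assemble the base population: natives plus introgressed foreigners.

    All founders are unrelated, non-inbred, and heterozygous for two unique
    alleles at every background locus.  Exogenous founder sexes are random;
    native founders complete the exact N/2 / N/2 sex ratio.
    """
    if N % 2:
        raise ValueError("N must be even")
    if not 0 <= n_exogenous <= N:
        raise ValueError("n_exogenous out of range")
    ped = Pedigree()
    ids = ped.add_founders(N)
    is_male = _assign_founder_sexes(N, n_exogenous, rng)
    origin_native = np.ones(N, dtype=bool)
    origin_native[:n_exogenous] = False

    L, M = gmap.n_loci, gmap.n_markers
    nonmarker = np.empty((N, 2, L), dtype=np.int32)
    marker = np.empty((N, 2, M), dtype=np.int8)
    for i in range(N):
        origin = "native" if origin_native[i] else "exogenous"
        g = build_founder_genome(i, origin, panel, gmap, rng)
        nonmarker[i, 0], nonmarker[i, 1] = g.hap_a.nonmarker_alleles, g.hap_b.nonmarker_alleles
        marker[i, 0], marker[i, 1] = g.hap_a.marker_alleles, g.hap_b.marker_alleles
    pop = Population(
        generation=0,
        ids=ids,
        is_male=is_male,
        nonmarker=nonmarker,
        marker=marker,
        origin_native=origin_native,
    )
    return pop, ped


def breed(
    pop: Population,
    ped: Pedigree,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Population:
    """Produce the next generation from per-offspring parent index pairs.

    One gamete is sampled from each parent per offspring; offspring sexes
    are exactly N/2 / N/2 assigned by random permutation (constant size and
    sex ratio every generation).
    """
    N = pop.size
    sire_idx = np.asarray(sire_idx)
    dam_idx = np.asarray(dam_idx)
    pat_nm, pat_mk = sample_gametes_array(
        pop.nonmarker[sire_idx, 0], pop.nonmarker[sire_idx, 1],
        pop.marker[sire_idx, 0], pop.marker[sire_idx, 1], gmap, rng,
    )
    mat_nm, mat_mk = sample_gametes_array(
        pop.nonmarker[dam_idx, 0], pop.nonmarker[dam_idx, 1],
        pop.marker[dam_idx, 0], pop.marker[dam_idx, 1], gmap, rng,
    )
    nonmarker = np.stack([pat_nm, mat_nm], axis=1)
    marker = np.stack([pat_mk, mat_mk], axis=1)
    is_male = np.zeros(N, dtype=bool)
    is_male[: N // 2] = True
    rng.shuffle(is_male)
    ids = ped.add_offspring(pop.ids[sire_idx], pop.ids[dam_idx], pop.generation + 1)
    return Population(
        generation=pop.generation + 1,
        ids=ids,
        is_male=is_male,
        nonmarker=nonmarker,
        marker=marker,
        origin_native=pop.origin_native,
    )


def admix_generation(
    pop: Population, ped: Pedigree, gmap: GeneticMap, rng: np.random.Generator
) -> Population:
    """One generation of unmanaged reproduction during the admixture period.

    Each offspring draws its sire uniformly with replacement from the
    males and its dam uniformly from the females.
    """
    males, females = pop.males(), pop.females()
    if males.size == 0 or females.size == 0:
        raise ValueError("need at least one parent of each sex")
    sire_idx = rng.choice(males, size=pop.size, replace=True)
    dam_idx = rng.choice(females, size=pop.size, replace=True)
    return breed(pop, ped, sire_idx, dam_idx, gmap, rng)
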