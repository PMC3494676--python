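"""Genome representation, founder construction and gamete formation.

The simulated genome is a single linear chromosome carrying two classes of
loci on one shared genetic map:

* ``L`` neutral multi-allelic *background* loci used only to measure the
  ancestry composition of the population (every founder carries two
  globally unique alleles at each of them, so the founder origin of every
  allele copy in any later generation is recoverable), and
* ``M`` *marker* loci whose genotypes drive the management decisions.

Gametes are formed with a Poisson number of crossovers (no interference),
so the expected number of crossovers equals the map length in Morgans and
two loci at map distance ``d`` recombine with Haldane's frequency
``(1 - exp(-2 d)) / 2``.  Markers and background loci are transmitted from
the *same* crossover realization, preserving the linkage disequilibrium
between them that makes partially-informative markers useful at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "Haplotype",
    "Genome",
    "build_founder_genome",
    "sample_gamete",
]


@dataclass(frozen=True)
class GeneticMap:
    """Positions (in Morgans) of background and marker loci on one chromosome.

    Background loci are placed evenly at ``(l + 0.5) * length / L`` and the
    ``M`` markers are interleaved evenly at ``(m + 0.5) * length / M``
    offset so that no marker coincides with a background locus.
    """

    length_morgans: float
    n_loci: int
    n_markers: int
    nonmarker_positions: np.ndarray = field(init=False, repr=False)
    marker_positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.length_morgans <= 0:
            raise ValueError("map length must be positive")
        if self.n_loci < 1 or self.n_markers < 1:
            raise ValueError("need at least one locus of each class")
        L, M = self.n_loci, self.n_markers
        nm = (np.arange(L) + 0.5) * self.length_morgans / L
        # tiny offset keeps marker coordinates distinct from background ones
        mk = (np.arange(M) + 0.5) * self.length_morgans / M
        mk = mk + 0.25 * self.length_morgans / max(L, M * 2)
        object.__setattr__(self, "nonmarker_positions", nm)
        object.__setattr__(self, "marker_positions", np.clip(mk, 0.0, self.length_morgans))


@dataclass
class Haplotype:
    """One gametic haplotype: background allele IDs plus marker alleles."""

    nonmarker_alleles: np.ndarray  # (L,) int32 founder allele IDs
    marker_alleles: np.ndarray  # (M,) int8 allele indices

    def copy(self) -> "Haplotype":
        return Haplotype(self.nonmarker_alleles.copy(), self.marker_alleles.copy())


@dataclass
class Genome:
    """A diploid genome: two haplotypes."""

    hap_a: Haplotype
    hap_b: Haplotype


def build_founder_genome(
    founder_index: int,
    origin: str,
    panel,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Genome:
    """Construct a founder genome.

    At every background locus the two allele copies get the globally unique
    IDs ``2*founder_index`` and ``2*founder_index + 1``; a base population
    of N founders therefore segregates 2N distinct alleles per locus and
    every founder is heterozygous everywhere.  Marker genotypes are drawn
    from the origin population's panel frequencies (see
    :func:`admixpurge.markers.draw_founder_marker_genotype`).
    """
    from .markers import draw_founder_marker_genotype

    L = gmap.n_loci
    a = np.full(L, 2 * founder_index, dtype=np.int32)
    b = np.full(L, 2 * founder_index + 1, dtype=np.int32)
    mk_a, mk_b = draw_founder_marker_genotype(panel, origin, rng)
    return Genome(Haplotype(a, mk_a), Haplotype(b, mk_b))


def _draw_crossovers(length: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(length) crossovers at uniform positions, sorted."""
    k = rng.poisson(length)
    if k == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0.0, length, size=k))


def _mosaic_sources(
    breakpoints: np.ndarray, start: int, positions: np.ndarray
) -> np.ndarray:
    """Which parental haplotype (0/1) each position inherits from.

    The chromosome is read left to right starting on haplotype ``start``
    and switching parity at every breakpoint.
    """
    seg = np.searchsorted(breakpoints, positions)
    return (start + seg) % 2


def sample_gamete(g: Genome, gmap: GeneticMap, rng: np.random.Generator) -> Haplotype:
    """Form one gamete by recombining the two haplotypes of ``g``.

    A single crossover realization governs both marker and background
    inheritance, so marker-background linkage is preserved.
    """
    breaks = _draw_crossovers(gmap.length_morgans, rng)
    start = int(rng.integers(2))
    src_nm = _mosaic_sources(breaks, start, gmap.nonmarker_positions)
    src_mk = _mosaic_sources(breaks, start, gmap.marker_positions)
    nm = np.where(src_nm == 0, g.hap_a.nonmarker_alleles, g.hap_b.nonmarker_alleles)
    mk = np.where(src_mk == 0, g.hap_a.marker_alleles, g.hap_b.marker_alleles)
    return Haplotype(nm.astype(np.int32), mk.astype(np.int8))


def sample_gametes_array(
    hap_a_nm: np.ndarray,
    hap_b_nm: np.ndarray,
    hap_a_mk: np.ndarray,
    hap_b_mk: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched gamete sampling for ``n`` parents given as stacked arrays.

    ``hap_*_nm`` are ``(n, L)`` and ``hap_*_mk`` are ``(n, M)``; one gamete
    is returned per row.  Crossover counts are drawn per gamete, so rows
    are independent realizations.
    """
    n = hap_a_nm.shape[0]
    out_nm = np.empty_like(hap_a_nm)
    out_mk = np.empty_like(hap_a_mk)
    ks = rng.poisson(gmap.length_morgans, size=n)
    starts = rng.integers(2, size=n)
    for i in range(n):
        if ks[i] == 0:
            src_nm = np.full(gmap.n_loci, starts[i])
            src_mk = np.full(gmap.n_markers, starts[i])
        else:
            breaks = np.sort(rng.uniform(0.0, gmap.length_morgans, size=ks[i]))
            src_nm = _mosaic_sources(breaks, starts[i], gmap.nonmarker_positions)
            src_mk = _mosaic_sources(breaks, starts[i], gmap.marker_positions)
        out_nm[i] = np.where(src_nm == 0, hap_a_nm[i], hap_b_nm[i])
        out_mk[i] = np.where(src_mk == 0, hap_a_mk[i], hap_b_mk[i])
    return out_nm, out_mk
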