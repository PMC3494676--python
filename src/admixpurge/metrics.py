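"""Per-generation outcome measurement.

The headline quantity is the *native representation* (NR): the fraction
of allele copies at the neutral background loci that descend from native
founders.  Because every founder allele is globally unique, NR is an
exact count, not an estimate.  Diversity costs of management are tracked
through pedigree inbreeding and mean coancestry, observed homozygosity at
the background loci (which here equals identity by descent, since the
base generation was fully heterozygous), and the effective population
size implied by the per-generation rate of inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Pedigree, Population

__all__ = [
    "MetricsRecord",
    "native_representation",
    "mean_inbreeding",
    "mean_coancestry",
    "observed_homozygosity",
    "effective_size",
    "measure",
]


@dataclass
class MetricsRecord:
    generation: int
    nr: float
    mean_f: float
    mean_coancestry: float
    obs_homozygosity: float
    ne: float
    n_contributing_parents: int | None = None

    def __post_init__(self) -> None:
        for name in ("nr", "mean_f", "mean_coancestry", "obs_homozygosity"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")


def native_representation(pop: Population) -> float:
    """Fraction of the 2*N*L background allele copies of native founder origin."""
    return float(pop.origin_native[pop.nonmarker // 2].mean())


def mean_inbreeding(ped: Pedigree, generation: int) -> float:
    """Mean pedigree F over the generation's individuals."""
    return float(ped.inbreeding(ped.members_of(generation)).mean())


def mean_coancestry(ped: Pedigree, generation: int) -> float:
    """Mean coancestry over all ordered pairs, self-pairs included."""
    return float(ped.kinship(ped.members_of(generation)).mean())


def observed_homozygosity(pop: Population) -> float:
    """Fraction of individual x background-locus genotypes that are homozygous.

    Founder alleles are unique, so any homozygote is identical by descent.
    """
    return float((pop.nonmarker[:, 0, :] == pop.nonmarker[:, 1, :]).mean())


def effective_size(f_prev: float, f_curr: float) -> float:
    """Ne = 1 / (2 dF) with dF = (F_t - F_{t-1}) / (1 - F_{t-1}).

    Returns inf when inbreeding did not increase.
    """
    df = (f_curr - f_prev) / (1.0 - f_prev)
    if df <= 0.0:
        return float("inf")
    return 1.0 / (2.0 * df)


def measure(
    pop: Population,
    ped: Pedigree,
    f_prev: float | None = None,
    n_contributing: int | None = None,
) -> MetricsRecord:
    """Snapshot all metrics for the population's current generation."""
    f = mean_inbreeding(ped, pop.generation)
    ne = effective_size(f_prev, f) if f_prev is not None else float("inf")
    return MetricsRecord(
        generation=pop.generation,
        nr=native_representation(pop),
        mean_f=f,
        mean_coancestry=mean_coancestry(ped, pop.generation),
        obs_homozygosity=observed_homozygosity(pop),
        ne=ne,
        n_contributing_parents=n_contributing,
    )
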