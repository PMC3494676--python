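"""Minimum-coancestry mate assignment.

Once per-parent offspring counts are fixed, each sire is expanded into as
many sire-slots as it has offspring (likewise for dams) and the N x N
linear assignment problem minimizing the summed pedigree coancestry of
the mated pairs is solved exactly (Hungarian algorithm via
``scipy.optimize.linear_sum_assignment``).  Slot order is shuffled with
the replicate RNG first so that ties among equally optimal assignments
are broken reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .management import ContributionPlan

__all__ = ["MatingList", "min_coancestry_matings"]


@dataclass
class MatingList:
    """One (sire, dam) pair per offspring; indices refer to the plan's parents."""

    sire_idx: np.ndarray  # (N,) entries drawn from plan.sire_idx
    dam_idx: np.ndarray  # (N,)

    @property
    def n(self) -> int:
        return self.sire_idx.size


def min_coancestry_matings(
    plan: ContributionPlan, kinship: np.ndarray, rng: np.random.Generator
) -> MatingList:
    """Pair sire-slots with dam-slots minimizing total parental coancestry.

    ``kinship[i, j]`` is the coancestry between the i-th entry of
    ``plan.sire_idx`` and the j-th entry of ``plan.dam_idx``.  The result
    realizes each parent's contribution count exactly and achieves the
    global assignment optimum.
    """
    if kinship.shape != (plan.sire_idx.size, plan.dam_idx.size):
        raise ValueError("kinship matrix does not cover the plan's parents")
    sire_slots = np.repeat(np.arange(plan.sire_idx.size), plan.sire_counts)
    dam_slots = np.repeat(np.arange(plan.dam_idx.size), plan.dam_counts)
    if sire_slots.size != dam_slots.size:
        raise ValueError("sire and dam slot totals differ")
    rng.shuffle(sire_slots)
    rng.shuffle(dam_slots)
    cost = kinship[np.ix_(sire_slots, dam_slots)]
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows)
    return MatingList(
        sire_idx=plan.sire_idx[sire_slots[rows[order]]],
        dam_idx=plan.dam_idx[dam_slots[cols[order]]],
    )
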