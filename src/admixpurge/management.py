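"""De-introgression strategies: who breeds, and how much.

Two families of strategy are implemented, both operating only on marker
genotypes (the pedigree is recorded but never used to pick parents):

* **Native-allele-count truncation** (diagnostic / diagnostic-like
  markers): per sex, only the individuals carrying the maximum number of
  designated native-allele copies become parents, and the N offspring
  slots are allocated uniformly at random among them (optionally capped
  per parent).  Selecting per sex guarantees at least one sire and one
  dam.

* **Distance minimization** (non-diagnostic markers): integer offspring
  counts per candidate are chosen by simulated annealing to minimize a
  genetic distance between the native reference allele frequencies
  (assumed known without error) and the expected marker frequencies of the
  next generation.  Three objectives are available: the Cavalli-Sforza &
  Edwards chord distance, Nei's minimum distance, and the Kullback-Leibler
  divergence D(reference || expected).

Expected next-generation frequencies follow from the gamete transmission
probabilities: an individual transmits allele ``a`` with probability 1,
0.5 or 0 according to whether it is homozygous, heterozygous or a
non-carrier, and each sex supplies half of the gene pool:

    p'_am = 1/2 * sum_males (c_i / N) g_iam + 1/2 * sum_females (c_i / N) g_iam
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markers import MarkerPanel
from .population import Individual, Population

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "ContributionPlan",
    "DistanceObjective",
    "SASchedule",
    "count_native_alleles",
    "native_allele_counts",
    "select_max_native",
    "allocate_contributions_random",
    "truncation_plan",
    "gamete_allele_probs",
    "expected_frequencies",
    "distance",
    "optimize_contributions_sa",
]

DISTANCE_KINDS = ("chord", "nei_min", "kl")
_KIND_CODE = {"chord": 0, "nei_min": 1, "kl": 2}
KL_FLOOR = 1e-9


class InfeasibleCapError(ValueError):
    """Raised when the offspring cap cannot supply N slots from the selected set."""


@dataclass
class ContributionPlan:
    """Integer offspring counts per parent, split by sex.

    ``sire_idx`` / ``dam_idx`` are row indices into the population the plan
    was built for; counts sum to N within each sex (each offspring has one
    sire and one dam).
    """

    sire_idx: np.ndarray
    sire_counts: np.ndarray
    dam_idx: np.ndarray
    dam_counts: np.ndarray
    N: int

    def __post_init__(self) -> None:
        for counts in (self.sire_counts, self.dam_counts):
            if counts.sum() != self.N:
                raise ValueError("per-sex contributions must sum to N")
            if (counts < 0).any():
                raise ValueError("contributions must be non-negative")
        if (self.sire_counts > 0).sum() < 1 or (self.dam_counts > 0).sum() < 1:
            raise ValueError("need at least one contributing parent of each sex")

    @property
    def n_contributing(self) -> int:
        return int((self.sire_counts > 0).sum() + (self.dam_counts > 0).sum())


@dataclass(frozen=True)
class DistanceObjective:
    """A genetic distance to the native reference frequencies.

    ``reference`` is the (M, A) native frequency table from the marker
    panel; ``kind`` selects the formula.
    """

    kind: str
    reference: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in DISTANCE_KINDS:
            raise ValueError(f"kind must be one of {DISTANCE_KINDS}")
        if not np.allclose(self.reference.sum(axis=1), 1.0):
            raise ValueError("reference rows must sum to 1")


# ---------------------------------------------------------------------------
# truncation selection on native-allele counts


def count_native_alleles(ind: Individual, panel: MarkerPanel) -> int:
    """Number of designated native-allele copies (0..2M) carried by ``ind``."""
    idx = panel.native_allele_index
    g = ind.genome
    return int(
        (g.hap_a.marker_alleles == idx).sum() + (g.hap_b.marker_alleles == idx).sum()
    )


def native_allele_counts(pop: Population, panel: MarkerPanel) -> np.ndarray:
    """Vectorized native-allele counts for every individual in ``pop``."""
    idx = panel.native_allele_index[None, None, :]
    return (pop.marker == idx).sum(axis=(1, 2))


def select_max_native(pop: Population, panel: MarkerPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per sex, the individuals achieving that sex's maximum count.

    Selecting sex-wise maxima guarantees at least one sire and one dam
    even when the global maximum occurs in only one sex.
    """
    counts = native_allele_counts(pop, panel)
    males, females = pop.males(), pop.females()
    sel_m = males[counts[males] == counts[males].max()]
    sel_f = females[counts[females] == counts[females].max()]
    return sel_m, sel_f


def _allocate_slots(
    selected: np.ndarray, N: int, cap: int | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign N slots uniformly with replacement, respecting the cap."""
    k = selected.size
    eff_cap = N if cap is None else int(cap)
    if k * eff_cap < N:
        raise InfeasibleCapError(
            f"{k} selected parents cannot supply {N} slots at cap {eff_cap}"
        )
    counts = np.zeros(k, dtype=np.int64)
    open_idx = np.arange(k)
    for _ in range(N):
        pick = open_idx[rng.integers(open_idx.size)]
        counts[pick] += 1
        if counts[pick] >= eff_cap:
            open_idx = open_idx[open_idx != pick]
    return selected, counts


def allocate_contributions_random(
    selected_males: np.ndarray,
    selected_females: np.ndarray,
    N: int,
    cap: int | None,
    rng: np.random.Generator,
) -> ContributionPlan:
    """Random allocation of the N sire slots and N dam slots.

    Contributions within the selected subset are uniform with replacement,
    so they differ between individuals by chance, as intended.  Raises
    :class:`InfeasibleCapError` when the cap times the selected count
    cannot cover N slots for either sex.
    """
    m_idx, m_counts = _allocate_slots(np.asarray(selected_males), N, cap, rng)
    f_idx, f_counts = _allocate_slots(np.asarray(selected_females), N, cap, rng)
    return ContributionPlan(m_idx, m_counts, f_idx, f_counts, N)


def truncation_plan(
    pop: Population,
    panel: MarkerPanel,
    cap: int | None,
    rng: np.random.Generator,
) -> ContributionPlan:
    """Max-native-count selection with cap-infeasibility tier relaxation.

    When an offspring cap leaves too few top-tier parents to supply N
    slots, the next-best native-allele-count tier is admitted (repeatedly
    if needed) so the population size stays constant.
    """
    N = pop.size
    counts = native_allele_counts(pop, panel)
    eff_cap = N if cap is None else int(cap)

    def tiers(sex_idx: np.ndarray) -> np.ndarray:
        levels = np.sort(np.unique(counts[sex_idx]))[::-1]
        selected = np.empty(0, dtype=np.int64)
        for lvl in levels:
            selected = np.concatenate([selected, sex_idx[counts[sex_idx] == lvl]])
            if selected.size * eff_cap >= N:
                break
        return selected

    sel_m, sel_f = tiers(pop.males()), tiers(pop.females())
    return allocate_contributions_random(sel_m, sel_f, N, cap, rng)


# ---------------------------------------------------------------------------
# expected frequencies and genetic distances


def gamete_allele_probs(marker_genotypes: np.ndarray, n_alleles: int) -> np.ndarray:
    """Per-individual gamete transmission probabilities g_iam, shape (n, M, A).

    1 for homozygotes aa, 0.5 for heterozygotes carrying a, 0 otherwise.
    """
    alleles = np.arange(n_alleles, dtype=marker_genotypes.dtype)
    hits = marker_genotypes[:, :, :, None] == alleles[None, None, None, :]
    return hits.sum(axis=1) / 2.0


def expected_frequencies(
    plan: ContributionPlan, marker_genotypes: np.ndarray, panel: MarkerPanel
) -> np.ndarray:
    """Expected next-generation marker frequencies p'_am under ``plan``.

    Each sex supplies half the gene pool; within a sex, individual i is
    weighted by its relative contribution c_i / N.
    """
    g = gamete_allele_probs(marker_genotypes, panel.alleles_per_marker)
    p_m = np.tensordot(plan.sire_counts, g[plan.sire_idx], axes=(0, 0))
    p_f = np.tensordot(plan.dam_counts, g[plan.dam_idx], axes=(0, 0))
    return (p_m + p_f) / (2.0 * plan.N)


def distance(obj: DistanceObjective, p: np.ndarray, p_prime: np.ndarray) -> float:
    """Evaluate the objective distance between frequency tables p and p'.

    Both are (M, A); all three distances are averaged over markers, a
    monotone rescaling that leaves the argmin unchanged.
    """
    if p.shape != p_prime.shape:
        raise ValueError("mismatched allele sets")
    return float(
        _objective(
            np.ascontiguousarray(p, dtype=np.float64).ravel(),
            np.ascontiguousarray(p_prime, dtype=np.float64).ravel(),
            _KIND_CODE[obj.kind],
            p.shape[0],
            p.shape[1],
        )
    )


@njit(cache=True)
def _objective(p_ref: np.ndarray, p: np.ndarray, kind: int, M: int, A: int) -> float:
    total = 0.0
    if kind == 0:  # Cavalli-Sforza & Edwards chord
        for m in range(M):
            s = 0.0
            for a in range(A):
                s += math.sqrt(p_ref[m * A + a] * max(p[m * A + a], 0.0))
            v = 2.0 * (1.0 - s)
            total += math.sqrt(v) if v > 0.0 else 0.0
        return 2.0 / (math.pi * M) * total
    elif kind == 1:  # Nei minimum
        for m in range(M):
            jx = 0.0
            jy = 0.0
            jxy = 0.0
            for a in range(A):
                jx += p_ref[m * A + a] ** 2
                jy += p[m * A + a] ** 2
                jxy += p_ref[m * A + a] * p[m * A + a]
            total += 0.5 * (jx + jy) - jxy
        return total / M
    else:  # Kullback-Leibler D(reference || expected)
        for m in range(M):
            for a in range(A):
                pr = p_ref[m * A + a]
                if pr > 0.0:
                    q = p[m * A + a]
                    if q < KL_FLOOR:
                        q = KL_FLOOR
                    total += pr * math.log(pr / q)
        return total / M


# ---------------------------------------------------------------------------
# simulated annealing over integer contributions


@dataclass(frozen=True)
class SASchedule:
    """Annealing schedule parameters.

    The initial temperature is calibrated so about half of the uphill
    moves sampled from the starting plan would be accepted; cooling is
    geometric with ``moves_per_temp_factor * n_candidates`` proposals per
    temperature step, stopping after ``stall_limit`` steps without
    improvement of the best plan (or at ``max_steps``).
    """

    moves_per_temp_factor: int = 100
    cooling: float = 0.95
    stall_limit: int = 50
    max_steps: int = 300
    pilot_moves: int = 200


@njit(cache=True)
def _anneal(
    gm: np.ndarray,  # (n_m, M*A) male gamete probs
    gf: np.ndarray,  # (n_f, M*A)
    cm: np.ndarray,  # (n_m,) initial male contributions
    cf: np.ndarray,  # (n_f,)
    p_ref: np.ndarray,  # (M*A,)
    kind: int,
    M: int,
    A: int,
    N: int,
    cap: int,
    cooling: float,
    moves_per_temp: int,
    stall_limit: int,
    max_steps: int,
    pilot_moves: int,
    seed: int,
):
    np.random.seed(seed)
    n_m, n_f = gm.shape[0], gf.shape[0]
    denom = 2.0 * N
    p = np.zeros(M * A)
    for i in range(n_m):
        if cm[i] > 0:
            for k in range(M * A):
                p[k] += cm[i] * gm[i, k] / denom
    for i in range(n_f):
        if cf[i] > 0:
            for k in range(M * A):
                p[k] += cf[i] * gf[i, k] / denom
    energy = _objective(p_ref, p, kind, M, A)
    best_e = energy
    best_cm = cm.copy()
    best_cf = cf.copy()

    # a sex whose every candidate sits at the cap admits no transfer move
    m_free = n_m * cap > N and n_m > 1
    f_free = n_f * cap > N and n_f > 1
    if not (m_free or f_free):
        return best_cm, best_cf, best_e

    # pilot: mean uphill delta from the initial plan sets T0 (~50% acceptance)
    up_sum = 0.0
    up_n = 0
    pnew = np.empty(M * A)
    for _ in range(pilot_moves):
        if m_free and (not f_free or np.random.random() < 0.5):
            g, c, n = gm, cm, n_m
        else:
            g, c, n = gf, cf, n_f
        i = np.random.randint(n)
        j = np.random.randint(n)
        while c[i] == 0 or j == i or c[j] >= cap:
            i = np.random.randint(n)
            j = np.random.randint(n)
        for k in range(M * A):
            pnew[k] = p[k] + (g[j, k] - g[i, k]) / denom
        de = _objective(p_ref, pnew, kind, M, A) - energy
        if de > 0.0:
            up_sum += de
            up_n += 1
    temp = (up_sum / up_n) / math.log(2.0) if up_n > 0 else 1e-8

    stall = 0
    for _ in range(max_steps):
        improved = False
        for _ in range(moves_per_temp):
            if m_free and (not f_free or np.random.random() < 0.5):
                g, c, n = gm, cm, n_m
            else:
                g, c, n = gf, cf, n_f
            i = np.random.randint(n)
            j = np.random.randint(n)
            while c[i] == 0 or j == i or c[j] >= cap:
                i = np.random.randint(n)
                j = np.random.randint(n)
            for k in range(M * A):
                pnew[k] = p[k] + (g[j, k] - g[i, k]) / denom
            e_new = _objective(p_ref, pnew, kind, M, A)
            de = e_new - energy
            if de <= 0.0 or np.random.random() < math.exp(-de / temp):
                c[i] -= 1
                c[j] += 1
                for k in range(M * A):
                    p[k] = pnew[k]
                energy = e_new
                if energy < best_e - 1e-15:
                    best_e = energy
                    best_cm = cm.copy()
                    best_cf = cf.copy()
                    improved = True
        # drift control: refresh p from the integer counts
        for k in range(M * A):
            p[k] = 0.0
        for i in range(n_m):
            if cm[i] > 0:
                for k in range(M * A):
                    p[k] += cm[i] * gm[i, k] / denom
        for i in range(n_f):
            if cf[i] > 0:
                for k in range(M * A):
                    p[k] += cf[i] * gf[i, k] / denom
        energy = _objective(p_ref, p, kind, M, A)
        temp *= cooling
        stall = 0 if improved else stall + 1
        if stall >= stall_limit:
            break
    return best_cm, best_cf, best_e


def _equal_plan(n: int, N: int, cap: int, rng: np.random.Generator) -> np.ndarray:
    """As-equal-as-possible integer contributions summing to N under the cap."""
    if n * cap < N:
        raise InfeasibleCapError(f"{n} candidates cannot supply {N} slots at cap {cap}")
    c = np.full(n, N // n, dtype=np.int64)
    extra = rng.permutation(n)[: N % n]
    c[extra] += 1
    while (c > cap).any():  # pragma: no cover - only when N/n exceeds cap
        hi = int(np.argmax(c))
        lo = int(np.argmin(c))
        move = c[hi] - cap
        c[hi] -= move
        c[lo] += move
    return c


def optimize_contributions_sa(
    pop: Population,
    obj: DistanceObjective,
    cap: int | None,
    rng: np.random.Generator,
    schedule: SASchedule = SASchedule(),
) -> ContributionPlan:
    """Minimize the expected genetic distance by simulated annealing.

    Starts from (near-)equal contributions, proposes single-slot transfers
    between two same-sex parents, and accepts uphill moves with
    probability exp(-delta/T) under geometric cooling.  The returned plan
    is the best feasible plan seen, so it is never worse than the
    equal-contribution start.
    """
    N = pop.size
    males, females = pop.males(), pop.females()
    eff_cap = N if cap is None else int(cap)
    g = gamete_allele_probs(pop.marker, obj.reference.shape[1])
    MA = obj.reference.size
    gm = np.ascontiguousarray(g[males].reshape(males.size, MA))
    gf = np.ascontiguousarray(g[females].reshape(females.size, MA))
    cm0 = _equal_plan(males.size, N, eff_cap, rng)
    cf0 = _equal_plan(females.size, N, eff_cap, rng)
    seed = int(rng.integers(2**31 - 1))
    M, A = obj.reference.shape
    cm, cf, _ = _anneal(
        gm, gf, cm0.copy(), cf0.copy(),
        np.ascontiguousarray(obj.reference, dtype=np.float64).ravel(),
        _KIND_CODE[obj.kind], M, A, N, eff_cap,
        schedule.cooling,
        schedule.moves_per_temp_factor * (males.size + females.size),
        schedule.stall_limit, schedule.max_steps, schedule.pilot_moves, seed,
    )
    keep_m, keep_f = cm > 0, cf > 0
    return ContributionPlan(
        males[keep_m], cm[keep_m], females[keep_f], cf[keep_f], N
    )
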