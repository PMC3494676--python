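# Methods

## Model overview

The simulator is individual-based and forward-in-time with discrete,
non-overlapping generations, constant census size N and an exact 1:1 sex
ratio.  A scenario has three phases:

1. **Founding (generation 0).** N founders, of which `n_exogenous` are
   foreign immigrants.  Exogenous founder sexes are drawn Bernoulli(½)
   and native founders fill the remaining N/2-per-sex quota (redrawn in
   the rare case one sex's exogenous count alone exceeds N/2), so
   immigrant sexes are random while the population sex ratio stays exact.
   All founders are unrelated and non-inbred.
2. **Admixture.** 1–5 generations of unmanaged reproduction: each of the
   N offspring draws its sire uniformly with replacement from the males
   and its dam from the females.
3. **Management.** 10 generations in which a strategy chooses per-parent
   offspring counts from marker genotypes only, minimum-coancestry
   matings realize those counts, and each mating produces one offspring.

## Genome and recombination

One chromosome of length λ Morgans (default 20; 1 supported for a
high-LD variant) carries L = 2000 neutral background loci placed evenly
at (ℓ+0.5)·λ/L and M = 5–20 markers interleaved evenly on the same map at
distinct coordinates.  Every founder receives two globally unique allele
IDs at each background locus (encoded 2·founder_index + copy), so the
base generation segregates 2N alleles per locus, every founder is fully
heterozygous, and the founder origin of any allele copy in any generation
is an O(1) lookup.  Gametes receive a Poisson(λ) number of crossovers at
uniform positions with no interference (Haldane model); a single
crossover realization governs both marker and background inheritance, so
the linkage disequilibrium between markers and background — the only
reason partially informative markers purge anything — is preserved.
Mutation, selection on the background loci, and multiple chromosomes are
deliberately absent.

## Marker panels

Base-population allele frequencies per scheme:

| scheme                | native              | exogenous           |
|-----------------------|---------------------|---------------------|
| diagnostic            | 1, 0                | 0, 1                |
| diagnostic_like       | 0.80, 0.20          | 0.20, 0.80          |
| extra_diagnostic_like | f, 1−f (f ∈ 0.7–0.99)| 0.50, 0.50         |
| non_diagnostic        | 0.80, 0.07, 0.06, 0.07 | 0.07, 0.80, 0.06, 0.07 |

Diagnostic founders are deterministically homozygous for their private
allele.  Under the other schemes the two allele copies of each founder
are drawn independently from the origin population's frequencies
(Hardy–Weinberg, no within-population LD among markers at generation 0 —
the simplest model consistent with stated population frequencies; LD then
builds up through admixture).  Allele labels are shared between
populations.  Arbitrary frequency tables are accepted through
`custom_panel`; the "native" allele is then the most frequent native
allele per marker.

## Management strategies

**Truncation on native-allele counts.**  An individual's score is its
number of designated-native-allele copies over all markers (0..2M).
Selection takes, within each sex, all individuals achieving that sex's
maximum score (guaranteeing at least one sire and one dam; ties all
enter, which makes the method effectively random once scores fix).  The
N sire slots are then assigned uniformly at random with replacement among
selected males (likewise dams), subject to the optional per-parent
offspring cap.  If the cap makes the top tier infeasible
(cap × selected < N), the next score tier is admitted, repeatedly if
necessary — population size is a hard constraint.

**Distance minimization.**  The expected next-generation frequency is
linear in the integer contributions, p′ = ½·Σ_males (c_i/N)·g_i +
½·Σ_females (c_i/N)·g_i; each sex supplies half the gene pool, which
coincides with the plain c-weighted sum whenever the sexes contribute
equally, as the breeding design mandates.  Objectives (all averaged over
the M markers — a monotone rescaling that leaves the argmin unchanged but
makes values comparable across panel sizes):

* chord: (2/(πM))·Σ_m √(2(1 − Σ_a √(p_am p′_am)))
* nei_min: (1/M)·Σ_m [(Σ_a p_am² + Σ_a p′_am²)/2 − Σ_a p_am p′_am]
* kl: (1/M)·Σ_m Σ_a p_am ln(p_am/p′_am), direction D(reference ‖ expected),
  with 0·ln(0/x) = 0 and p′ floored at ε = 10⁻⁹ inside the log.  Without
  the floor, any plan eliminating a reference allele scores +∞; that
  strong penalty is desirable, the floor merely bounds it.

Contributions are integer offspring counts (what reproduction physically
requires), per sex summing to N, optimized by simulated annealing:

* move: transfer one offspring slot between two same-sex parents
  (donor/recipient pair drawn jointly by rejection; a sex saturated at
  the cap admits no moves);
* start: (near-)equal contributions;
* initial temperature: calibrated from 200 pilot moves so that roughly
  half of uphill moves would be accepted;
* cooling: geometric, factor 0.95, with 100 × (number of candidates)
  proposals per temperature step;
* stop: 50 consecutive steps without improving the best plan, or 300
  steps.

All schedule constants are configurable (`SASchedule`).  The returned
plan is the best feasible plan encountered, hence never worse than the
equal-contribution start.  The inner loop is compiled with numba; the
annealer is seeded from the replicate RNG so runs are reproducible.

**Mating.**  Sires and dams are expanded into contribution-many slots and
the N×N assignment minimizing summed pedigree coancestry of the pairs is
solved exactly with `scipy.optimize.linear_sum_assignment`.  Slot order
is shuffled with the replicate RNG beforehand so that ties among optimal
assignments break reproducibly.  Full-sib-mating avoidance beyond the
coancestry objective is not imposed.

## Pedigree and metrics

Coancestry uses the tabular method (founders f(i,i)=½, f(i,j)=0;
offspring rows by the standard ½/¼ recursions), maintained incrementally
as cohorts are appended.  Reported per generation:

* **NR** — fraction of the 2NL background allele copies of native founder
  origin; exact by construction (equals 1 − introgression fraction at
  generation 0).
* **mean F** — mean pedigree inbreeding of the cohort.
* **mean coancestry** — mean over all N² ordered pairs *including*
  self-coancestries (the "group coancestry" convention; only trends are
  compared, and the convention is fixed and documented).  The expected
  trend is non-decreasing in a closed population; single realizations can
  dip slightly when the sampled parents are less related than the cohort
  average, so tests check the replicate-averaged trend.
* **observed homozygosity** — fraction of homozygous background
  genotypes; with fully heterozygous founders this is exactly the
  identity-by-descent rate and tracks mean F.
* **Ne** — 1/(2ΔF) with ΔF = (F_t − F_{t−1})/(1 − F_{t−1}); reported as
  ∞ when inbreeding did not increase.
* number of contributing parents (useful to interpret the Ne trajectory:
  few parents early in management, many once marker scores fix).

## Reproducibility and problem sizes

One seeded `numpy` generator drives each replicate; the replicate seed is
`base_seed + replicate_index`, so any replicate is re-runnable in
isolation and identical seeds give bit-identical metric tables.

Benchmark scenarios (test suite and `scripts/acceptance.py`) run at the
full study scale — N=100, L=2000, λ=20 M, 20 markers, 5 admixture + 10
managed generations, 20 replicates — which completes in seconds per
truncation scenario and a few minutes for an annealing scenario.  The
qualitative-ordering checks (scheme ranking, cap effects) use a reduced
grid of 6 replicates at two introgression levels with a shortened
annealing schedule; these are the package's own choices of check size,
adequate because the effects compared are large relative to Monte-Carlo
error at those sizes.

## What the generator does and does not emulate

The synthetic populations realize the study conditions exactly: known
founder origins, fully informative background loci, markers at their
nominal base frequencies, random immigrant sexes, constant N.  Real
de-introgression programs differ in ways the simulator deliberately
ignores: genotyping error, unknown or misestimated reference frequencies
(the reference is "known without error" here), overlapping generations,
mortality and fecundity limits beyond the offspring cap, multiple
chromosomes, and selection or linkage to fitness loci.  Passing results
therefore demonstrate properties of the management algorithms under
idealized information, not field performance guarantees.

## Known limitations

* Pedigree coancestry is kept as one dense matrix over all individuals
  ever recorded (~(16N)² doubles per replicate) — ample at study sizes,
  wasteful for N ≫ 10³.
* The annealer treats the two sexes' contribution vectors as one state;
  no restarts are attempted.  On enumerable instances it matches the
  exhaustive optimum, but global optimality on large instances is, as
  with any annealer, heuristic.
* `effective_size` is undefined (∞) for non-increasing F; no harmonic
  averaging across generations is provided.
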