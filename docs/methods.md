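# Model and methods

## The system

The rDNA locus is modeled as an ordered array of categorical units.  Each
unit is uninserted, carries a full-length R2 retrotransposon, or carries a
5'-truncated (dead-on-arrival) copy.  Truncated copies block their unit for
transcription-domain and fitness purposes but cannot generate new
insertions.  Every insertion event receives a unique integer lineage label;
a label present more than once within a locus was duplicated by unequal
crossover, which is how the simulated duplication spectra mirror the PCR
truncation assay applied to fly lines.

Populations are sexed with X-linked inheritance in simplified form: exactly
N/2 females (two loci each) and N/2 males (one locus), with an unsexed
gamete pool.  Each generation 3N/2 chromosomes are drawn from the pool
without replacement; the first N are paired into females, the rest become
males.

## The transcription domain

Each generation, every locus activates one contiguous window of `domain_size`
units (females: half that size on each of their two loci).  The window is
centered on the largest contiguous run of uninserted units — leftmost run on
ties, midpoint rounded to the nearest unit with exact halves toward the
lower index, window clamped inside the locus, whole locus if the locus is
smaller than the domain, locus midpoint if no unit is free.  A locus whose
largest free run is at least as large as its domain is R2-silent; otherwise
inserted units fall inside the window and are transcribed.  Two activity
notions follow and both are exposed: *transcriptional* activity (any
inserted unit in the window) and *retrotranspositional* competence (at least
one full-length element in the window).  All reported "fraction R2-active"
statistics use the full-length definition, at the individual level for the
by-sex fractions (a female is active if either locus qualifies).

## Per-generation lifecycle

Fixed event order (the contract for reproducibility):

1. domain placement on every chromosome;
2. retrotransposition — per individual, the expected event count is
   `p * sqrt(n_FL)` with `n_FL` the full-length count pooled over the
   individual's domain(s); the realized count is Poisson; each event picks a
   target chromosome uniformly, is truncated with probability 0.5, and
   lands on an uninserted unit (localized sampling with up to 1000 tries,
   else the event is dropped — insertions never overwrite);
3. loop deletions — per chromosome, probability
   `min(1, 7e-5 * L + 6.5e-3 * n_FL_domain)`; size uniform on 1..30; the
   segment midpoint is localized near the domain and clipped to the locus;
   at least one unit always survives;
4. interchromosomal exchange (ICE) between a female's two loci at rate 1e-4:
   loci aligned at their (locally re-placed) domain midpoints plus a random
   signed offset, cut at a localized boundary, both products kept;
5. domains re-placed;
6. fitness: gametes = `round(f_max * min(1, u / F_req))`, `u` = uninserted
   units in the individual's domain(s), halves rounded away from zero;
7. gamete pool built (each female gamete takes one of her chromosomes by
   fair coin) and 3N/2 chromosomes drawn without replacement (with
   replacement, plus a logged bottleneck, if the pool is smaller);
8. sister-chromatid exchange at transmission: each *gamete's* chromosome
   copy independently undergoes an SCE with probability `sce_rate` — one
   meiosis, one post-replication exchange opportunity — and transmits one
   of the two crossover products by fair coin.

Legacy modes change three things: fitness uses total uninserted units in
the individual's loci against a whole-locus requirement (default 100);
retrotransposition is Bernoulli (default 0.009) per locus containing a
full-length element, with uniform insertion position; crossover cuts and
deletion midpoints are uniform over the locus (`legacy_centered` instead
places cuts Normal around the locus midpoint).

## Crossover geometry

Cut positions are between-unit boundaries in `[0, L]`.  Two arrays aligned
with a signed offset `k` and cut at `cut_A` (so `cut_B = cut_A + k`)
recombine into products `A[:cut_A] + B[cut_B:]` and `B[:cut_B] + A[cut_A:]`;
for identical sister chromatids the products are `L - |k|` and `L + |k|`
units long, and any lineage wholly inside the offset window is deleted from
the short product and doubled in the long one.  `|k|` is uniform on
`1..max_offset`, sign fair.  Cut pairs that would produce an empty locus or
exceed buffer capacity are resampled up to 1000 times, then the event is
skipped and counted.

## Localization kernels

Events are placed with a rounded Normal draw, resampled while out of range
(1000 tries, then clamped).  Two scalings are used deliberately:

- **Crossover cuts**: sigma = `S * L` around the domain midpoint.  The S
  range (0.05 tight, 0.5 broad) is meant to span "cuts mostly within the
  domain" to "cuts across the whole locus", which only a locus-length
  scaling produces.  At S = 0.05 and equilibrium block sizes, cut windows
  only occasionally reach the R2-bearing flanks, which is what keeps ~85%
  of lineages single-copy.
- **Insertions and loop deletions**: sigma = `S * domain size` (defaults
  0.4 and 0.2, i.e. 16 and 8 units around a 40-unit male domain).  These
  are domain-proximal processes — insertion from transcribed elements,
  activity-induced deletion — and anchoring their spread to the domain
  keeps the feedback that regenerates R2-active chromosomes operating at
  any locus length.  With a locus-length scaling they become effectively
  uniform at realistic locus sizes (sigma ~ 90 units), the largest free
  block escapes upward by crossover drift, and R2 decays to loss in every
  parameterization we tested; the domain scaling is the design choice that
  yields the stable polymorphic equilibrium the model is about.

## Parameters (defaults = the reference domain-model set)

| parameter | default | units / meaning |
|---|---|---|
| `n_individuals` | 5000 | population size N (even; N/2 per sex) |
| `generations` | 50000 | generations per replicate |
| `domain_size` | 40 | male per-locus domain, units; females get half per locus |
| `fitness_units_required` | 34 | uninserted domain units for peak fecundity |
| `max_gametes` | 6 | gametes at peak fitness |
| `sce_rate` | 0.2 | SCE per transmitted chromosome per generation |
| `ice_rate` | 1e-4 | ICE per female per generation |
| `crossover_max_offset` | 11 | max alignment offset, units |
| `crossover_s` | 0.05 | cut localization, fraction of locus length |
| `deletion_rate_per_unit` | 7e-5 | loop-deletion probability per unit of locus |
| `element_deletion_rate` | 6.5e-3 | added probability per full-length domain element |
| `deletion_max_size` | 30 | deletion size uniform on 1..max, units |
| `deletion_s` | 0.2 | deletion-midpoint localization, fraction of domain size |
| `retro_probability` | 0.18 | scales Poisson mean `p * sqrt(n_FL)` |
| `truncation_fraction` | 0.5 | dead-on-arrival share of new copies |
| `retro_s` | 0.4 | insertion localization, fraction of domain size |
| `initial_locus_size` | 250 | founder locus length, units |
| `initial_insertion_fraction` | 0.2 | founder insertion density |
| `initial_truncation_fraction` | 0.5 | truncated share among founder insertions |

Founder loci are what the synthetic start generates: every locus 250 units
with 50 insertions at uniformly random distinct positions, each a unique
lineage, half truncated.  This emulates a population already near the
observed insertion density but with *unstructured* insertion positions; it
does not emulate the concerted, centrally-structured arrays real loci have,
so early generations include a transient while crossovers and deletions
build that structure.

## Numerical and implementation choices

- Unit encoding: one `int64` per unit — 0 uninserted, `+label` full-length,
  `-label` truncated; the population is a padded matrix with one row per
  chromosome, grown geometrically when crossover products approach
  capacity.
- The per-generation loop is a numba kernel using numba's internal random
  state, seeded once per replicate from
  `SeedSequence(master_seed, spawn_key=(replicate,))`; chunked kernel calls
  continue one stream, so chunk boundaries cannot affect trajectories and
  identical configs are bit-reproducible.  The operator-level API
  (`apply_sce`, `retrotranspose`, ...) takes numpy `Generator` handles and
  shares the structural kernels (run finding, placement, product
  construction) with the engine.
- Gamete rounding is half-away-from-zero; fecundity therefore moves in
  whole-gamete steps and insertions beyond the 6-unit slack are neutral
  until they accumulate.
- Deletions use the step-1 placements (updated incrementally by
  insertions); ICE re-places the two domains locally because earlier
  deletions may have shifted coordinates; SCE uses the step-5 placements.
- Degenerate inputs: single-unit loci are never deleted below one unit;
  offsets at least the locus length skip the SCE; fully inserted loci
  center their domain on the locus midpoint.

## Reduced problem sizes

Package-level checks and the results script run the model at N = 2000 for
3000 generations with 5 replicates (the equilibrium is insensitive to
population size in this range, and most parameter sets approach equilibrium
within a few thousand generations), plus smaller side runs for the
broad-localization contrast, loss-of-R2 perturbations and
founder-independence checks.  Replicate-to-replicate drift at this scale is
substantial, which is why all reported values are replicate averages.

## Known limitations

- **Absolute scale of the equilibrium.**  The intensive properties of the
  equilibrium — insertion density (~20%), single-copy lineage fraction
  (~85%), by-sex activity ordering (males above females), the legacy
  model's excess duplication — are robust.  The extensive scale is not:
  mean locus size equilibrates some 20-35% above five-to-six domain
  lengths, and mean R2 number scales up with it.  Locus size is only weakly
  mean-reverting (deletion drag against transmission-variance growth), so
  founder locus size is remembered for thousands of generations and
  different founder states do not reach a common size distribution at desk
  scale.
- **Perturbation fates.**  Zero insertion tolerance
  (`fitness_units_required = domain_size`) and low transposition
  probability (p < 0.05) suppress full-length R2 strongly but do not
  eliminate it within desk-scale runs; the insertion feedback outweighs
  per-insertion selection of order 1/34 per generation at these population
  sizes.
- The model has no nucleotide sequence, no gene conversion, no crossover
  interference, no overlapping generations, no mating structure, and the
  gamete pool is unsexed; none of these are needed for the questions the
  summaries address, but comparisons to pedigree-level data would be.
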