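# Methods

## Model and procedure

The package analyses niche partitioning in a bipartite plant–hummingbird
network on two axes: resource identity (trophic) and time of day (diel).
All inference is built on the mean pairwise Pianka overlap of a
species × resource utilization matrix and a Monte-Carlo comparison against a
randomization null that preserves the aspect of the data the hypothesis is
*not* about.

**Independent visits.** Camera detections are filtered to legitimate visits
and thinned with a 20-s independence rule: within each
(camera, hummingbird, plant) group, an event is kept iff at least 20 s
elapsed since the previously *kept* event.  Anchoring to the retained event
makes the rule deterministic and idempotent; the boundary is inclusive
(exactly 20 s counts as independent).  Grouping includes the camera because
independence is defined per focal flower; whether the rule should chain
across plants on one camera is not determinable from the field protocol, so
the grouping is exposed as a parameter (`DEDUP_GROUP`).

**Matrices.** M1 counts independent visits per hummingbird × plant.  M2 bins
them into 12 one-hour bins 06:00–18:00 ([17,18] closed on the right so a
dusk detection is counted) or 6 morning bins 06:00–12:00.  M3 multiplies
each plant's fitted per-flower hourly sugar production (mg) by its total
flower count summed over the monthly censuses.  The M3 hour grid defaults to
the 12 bin left-edges 06…17 to match M2's 12 columns; a 13-point grid
(06…18) is available via `hour_grid="13"` — Pianka means are insensitive to
a consistent grid choice.

**Nectar standardization.** Brix readings are adjusted to the 20 °C
reference with a standard sucrose-refractometry correction table (bilinear
interpolation in temperature and Brix; a zero reading is treated as no
solute at any temperature), then converted via mg/ml = 10·B·d(B) with
d(B) = 0.9982 + 3.85·10⁻³B + 1.66·10⁻⁵B² g/ml.  Dynamic-protocol flowers are
made comparable with cumulative ones by adding the previous slot's corrected
volume and carrying the concentration forward (a zero-volume slot inherits
the previous slot's values verbatim); a flag (`use_observed_concentration`)
keeps observed Brix where present, since the field description is ambiguous
on re-measurement.  Sugar mass is volume (ml) × concentration (mg/ml).

**Secretion curves.** Per species, sugar in µg (mg × 1000, rounded half-up
to integers per the measurement convention) is regressed on hour and hour²
with a Poisson GLM (log link, statsmodels IRLS); at least 3 distinct slots
are required and prediction outside the fitted hour range raises rather than
extrapolates.  Note a numerical consequence of the integer convention:
refitting *exact* curve values rounded to µg leaves a deterministic
quantization bias of up to ~3·10⁻³ in the recovered coefficients for
low-production species; the machinery itself (continuous response) recovers
coefficients to ~10⁻¹² and 95% Wald CIs cover the truth at nominal rate
under Poisson noise (both measured by `dielniche.calibration` and the
acceptance script).

**Null models.** RA3 permutes each row independently across columns,
preserving the row multiset (niche breadth, totals) while freeing the
column assignment — the right null for "did species choose *different*
plants?".  ROSARIO draws an independent uniform circular shift per row,
preserving each diel curve's shape and lag structure while freeing its
location — the right null for "did species act at *different* times?".
Circular wrapping is the default because it is the only edge treatment that
preserves shape exactly for every offset; a non-wrapping variant (offsets
restricted so the support stays inside the domain) and a coupled-offset
variant (one common shift — degenerate, since a common rotation leaves all
pairwise overlaps unchanged; kept to demonstrate exactly that) are available
for sensitivity analysis.  `p_partitioning` is the proportion of null means
**≥** the observed mean (randomizations with at most the observed
partitioning) and `p_overlap` the proportion ≤ observed; ties count in both
tails, so the two sum to at least 1.  Null distributions are computed
vectorized in batches, so 10,000 replicates on a 4 × 12 matrix take
milliseconds.

**Plant-level tests.** Plant pairs are classified by co-flowering (shared
flowering month) and pollinator sharing (some hummingbird with positive
counts for both in M1).  Group differences in pairwise Pianka values use the
Wilcoxon rank-sum test (scipy `mannwhitneyu`; W is the U statistic of the
focal group, matching R's `wilcox.test` convention), one-tailed with the
competition-hypothesis direction "focal group overlaps less"; exact
enumeration at small n, mid-ranks plus tie-corrected normal approximation
otherwise.  The Mantel test correlates |Δ anther height| with the Euclidean
distance between per-flower hourly production vectors (per-flower rather
than abundance-scaled, to keep the trait hypothesis separate from
abundance; `distance_metric="availability"` switches), one-tailed for
positive association, with p the proportion of sampled label permutations
whose r is at least the observed.  It is hand-rolled (a seeded generator is
required for reproducible pipelines) and cross-checked in the tests against
scikit-bio and exhaustive enumeration.

## Synthetic communities

`dielniche.synthetic` emulates the field campaign.  Visits per
pollinator–plant pair are independent inhomogeneous Poisson processes with
Gaussian rate curves truncated to 06:00–18:00 and normalized so the
amplitude *is* the expected independent visits per camera-day; each visit
spawns 0–3 extra detections 1–19 s later (exercising the 20-s rule) and a
small non-legitimate fraction (default 5%) exercises the legitimacy filter.
Nectar sugar is lognormal multiplicative noise (CV 0.2 by default) around
the species' log-quadratic curve; volumes and Brix are back-computed so that
standardization reproduces the target sugar mass, and the dynamic protocol
emits per-slot increments on repeated flower ids (zero increments where the
cumulative target declines — after harmonization these plateau, exactly as
the field correction would).  Presets: `aligned` (identical schedules, mean
Pianka 1 on expected rates), `segregated` (disjoint activity peaks and plant
blocks, mean Pianka ≈ 0), and `paper_like` (4 hummingbirds × 12 plants with
the packaged visit totals, nectar coefficients and anther heights; only two
flower totals are published — 103 and 3 — the other ten are synthetic
stand-ins, and the staggered 4-month flowering windows are likewise
invented so that both co-flowering and non-co-flowering pairs exist).

What the generator does *not* emulate: weather- and season-driven rate
variation, visitor depletion of standing crop, inter-individual plant
variation in curve shape, spatial transect structure, and detection failure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated stochastic model, not robustness to those field
realities.

## Numerical choices and degenerate inputs

* Randomness: every stochastic routine takes a seed or `numpy` Generator;
  generator streams are derived per (seed, purpose, label) via `SeedSequence`
  with CRC-32 tokens, so outputs are bit-for-bit reproducible.
* Zero-sum utilization rows are an error naming the row (overlap is
  undefined); a zero Brix reading maps to 0 mg/ml; an empty event table
  yields an empty, warned-about matrix; a single-column ROSARIO matrix is
  the identity with a warning; a zero-variance distance matrix yields a
  flagged degenerate Mantel result rather than an exception.
* Flower-count scaling for dense plants rounds half-up to the nearest
  integer, as does the µg response.
* Monte-Carlo p-values are unsmoothed proportions of the requested
  replicates (no +1 correction), matching the definition used for the
  reported values; the calibration study confirms the resulting test is
  nominal at α = 0.05 to within binomial error at 1,000 datasets × 1,000
  replicates, the study size also used by the acceptance script.

## Known limitations

* The pairwise-mean test statistic ignores higher-order structure; only the
  community mean is tested, as in the original design.
* The dynamic-protocol harmonization cannot recover production declines
  (carry-forward censors them), so species measured dynamically have
  flattened afternoon tails — a property of the field protocol, reproduced
  faithfully.
* The Brix correction table is interpolated/extrapolated linearly outside
  10–40 °C and the density polynomial assumes pure sucrose; non-sugar
  solutes are not corrected for.
* Daily nectar totals depend on an aggregation convention (integration grid
  and period) that is not standardized here; the pipeline reports hourly
  values only.
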