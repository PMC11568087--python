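# Methods

This note documents the models, parameter choices and numerical conventions
behind `equiscape`, and what the synthetic study area does and does not
emulate.

## Units of analysis and the synthetic study area

The unit of analysis is the kebele, the smallest administrative unit in the
Ethiopian highland landscapes the package is modeled on. The default
generator draws 66 kebeles from four archetype templates sized 12, 19, 17
and 18 (accessible-wealthy, khat-cropland, pasture-cropland,
woody-vegetation). Kebele areas and populations are log-normal with means
30 km² and 4000 inhabitants (log-scale σ = 0.35, a typical dispersion for
administrative units); populations are rounded and floored at 1.

Each kebele carries nine social-ecological variables on [0, 1]
(woody-vegetation cover, coffee-forest availability, khat area, arable
area, pasture area, eucalyptus area, wealth index, accessibility, honey
importance). These are the template centroid plus Gaussian noise with sd =
`noise_sd` × the variable range (default 0.05), clipped to [0, 1]. The
centroids encode the qualitative orderings of the archetypes (e.g. the
khat-cropland template has the maximum khat and minimum wealth), so
clustering has a recoverable ground truth.

The LULC raster uses seven classes (forest, woody vegetation, cropland,
pasture, khat, eucalyptus, plantation coffee). Kebele zones are contiguous
boustrophedon strips sized by the drawn areas; within each zone, class
quotas are apportioned from the template mixture by largest remainder and
filled by seeded-patch region growing (one random seed per class, frontier
cells claimed with probability proportional to the remaining quota,
re-seeding when a patch is enclosed). Quotas are met exactly, so per-kebele
class fractions match the mixture to rounding; the mixtures are chosen so
the landscape is roughly half forest. The default cell size is 100 m.
Multi-seed tests and the recovery analysis use 500 m cells — the package's
choice of problem size for repeated runs — which leaves the kebele feature
table (and hence clustering) unchanged.

The plural-value survey simulates 164 respondents scoring each ES on an
ordinal 0–4 scale for four value types (direct use, exchange, relational,
intrinsic), drawn Binomial(4, mode/4) around ES-specific modes; the
aggregate weight is mean score / 4 ∈ [0, 1]. Stakeholder counts for
GO/PO/CBO/NGO start government-dominated at the baseline and shift
multiplicatively per scenario (private organisations grow under the two
cash-economy scenarios, community-based and non-governmental organisations
under the two conservation-leaning ones).

What the generator does **not** emulate: the spatial geometry of real
kebeles (strips, not watersheds), spatial autocorrelation *between*
kebeles' variables, measurement error structure of real surveys, or the
statistical detail of any real deposited dataset — only its structure.
Passing tests therefore demonstrate correctness of the pipeline's
computations and recoverability under controlled noise, not predictive
validity on real landscapes.

## Archetype clustering

Features are min-max scaled per column (constant columns map to 0.5 with a
warning; z-score is available). Clustering is agglomerative Ward linkage on
Euclidean distances, cut at k = 4 by default. The agglomeration is
implemented directly with O(n³) Lance–Williams updates — negligible cost at
n = 66 — because that makes the tie-break specifiable: at equal linkage
distance the lexicographically smallest cluster-id pair merges first.
Heights follow the convention in which the distance between singletons is
their Euclidean distance (verified against an independent reference
implementation on tie-free data). Labels are assigned by descending cluster
size; profiles are member means and naming suggestions list the variables
on which an archetype is extreme across archetypes.

## Scenario engine

A rule converts `ceil(area_ha·10⁴ / cell²)` candidate cells (its
convertible classes, optionally restricted to a kebele scope) to a target
class, ranked by Euclidean distance on cell centers to the nearest focal
cell (`scipy.ndimage.distance_transform_edt`), ascending or descending,
ties broken by (row, col). Rules apply sequentially, each on the previous
output; shape, nodata mask and total cell count are conserved. A rule with
no candidates warns and reports zero conversions rather than failing. The
rule validator requires a strictly positive hectare budget; a no-op is
expressed as a scenario with no rules. The four shipped example scenarios
encode the narratives qualitatively with budgets scaled to the landscape
(1–6% of its area); they are illustrative and user-editable via the YAML
rule format.

## ES provision

Each of the 11 ES uses a linear predictor over class areas (units per ha)
and social covariates, floored at zero with flooring logged. The shipped
default coefficients encode the obvious couplings (cereals ← cropland,
livestock ← pasture, forest-linked services ← forest/woody, khat and
plantation coffee ← their own classes) with two small positive social
covariates (honey importance, coffee-forest availability). Aggregation to
archetypes is the unweighted mean over member kebeles, and the study-area
value is the mean over all kebeles (not the mean of archetype means);
population-weighted means are deliberately not the default.

## Specialization, values, stakeholders

Adjusted provision is per-area density → log(1+x) → min-max per ES. log1p
is used because provision can be exactly zero and the transformation must
be defined there. The min-max is pooled over baseline and all scenarios per
ES so that states share one scale; per-state scaling would force an
artifactual maximum of 1 in every state and break change detection. A
column constant across the pool scales to 0 with a warning.

Specialization is Simpson concentration λ = Σ p² over the kebele's adjusted
shares — λ = 1 for a single-ES kebele, 1/11 for a uniform one. λ is
reported as concentration (higher = more specialized), not as diversity
1 − λ; the score is scale-invariant per kebele and kebeles with all-zero
adjusted provision are flagged missing rather than scored 0. Value
importance is `importance(k,v) = Σ_s w(s,v)·m(k,s)` with m the pooled
min-max-scaled per-capita provision and w the baseline-elicited weights,
reused for all scenarios (values are elicited once, at the baseline).
Stakeholder presence is kept at study-area level only.

## Levels, changes, summaries

Per aspect, all (kebele, state) values are pooled and split into seven
equal-frequency groups (three for stakeholder aspects); sizes differ by at
most one, with the larger groups at the low end, and ties break
deterministically by unit id then state order. Equal counts mean tied
values can straddle a boundary — accepted and documented; the alternative
(equal-width or tie-merged bins) would break the equal-group-size contract.
Change classes: Δ ∈ +4..+6 increase, +1..+3 moderate increase, 0 no change,
−1..−2 moderate decrease, and everything ≤ −3 decrease (the −5/−6 cases are
folded into "decrease" by declared extension); three-level aspects use ±1
moderate, ±2 strong.

Archetype and study-area cells are computed as the *level of the mean*:
the unweighted mean of member values is placed into the septile intervals
fixed by the kebele-level pooled data (boundary ties resolve to the lower
level), so aggregate cells are directly comparable to kebele levels.
Summaries are the mean and population standard deviation (ddof = 0) of the
cell levels over the 15 ES + value-type aspects per (aggregate, state).

## Determinism and I/O

One global seed drives everything; the pipeline expands it into per-step
seeds by fixed offsets so a step's randomness does not depend on which
other steps run. Reruns are byte-identical; the run manifest records
SHA-256 hashes of every artifact. Rasters are single-band integer TIFFs
with a GDAL_NODATA tag and CSV/JSON sidecars for legends and cell size;
coordinates are row/col with row 0 at north and areas come from cell
counts, so no CRS machinery is needed at desk scale. Reporting polygons are
derived from the zone raster (per-row run rectangles, unioned) and written
as GeoJSON.

## Known limitations

- Scenario hectare budgets and ES coefficients are illustrative defaults,
  not estimates from field data; both are user-replaceable files.
- Equal-frequency binning with heavy ties can place equal kebele values in
  adjacent levels (unit-level change arrows of ±1 near boundaries should be
  read with that in mind); aggregate cells are immune because they are
  interval lookups.
- The proximity rules are greedy and sequential; no optimization or
  interaction between rules is attempted.
- No reprojection, vector overlay, or remote-sensing classification; the
  baseline map is an input.
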