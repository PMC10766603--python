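# Methods

This note documents the models and procedures implemented by `trawlkit`,
their assumptions, the defaults that matter, and the design choices made
where the problem was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and quality rules

A survey table carries one row per taxon per haul. In memory this splits
into a haul frame (position, date, gear, effort) and a catch frame
(verbatim and harmonized taxonomy, abundance `num`, weight `wgt` in kg,
standardized rates). Units are fixed throughout: degrees WGS84, metres for
depth and gear opening, minutes for haul duration, km for distance, knots
for speed, km² for swept area, CPUE per hour, CPUA per km².

A haul is usable when it has both coordinates within bounds, a full
calendar date, a gear code, and at least one effort proxy (duration or
swept area) — either suffices. Depth is recorded but not mandatory. The
dataset-level filter additionally drops hauls the source marked invalid,
hauls not taken with otter trawls (beam trawls sample a different
community with different catchability and are out of scope beyond
flag-and-drop), hauls whose catch rows are all empty in both `num` and
`wgt`, and individual records with negative values. Negative abundances or
weights can only be corruption, so they are removed, not zeroed; null
(zero) catches are legitimate absences and are kept. Filtering is
idempotent, and because the "no catch values" rule is part of it, the
pipeline re-applies the filter after taxonomic harmonization so hauls
emptied by unmatched-name removal drop out with both counts on record.

## Taxonomic harmonization

Names are resolved against a user-supplied snapshot of a marine taxonomic
register (an AphiaID-style backbone table), pinned by content hash in the
provenance log; no live web services are queried, so results are
reproducible. Resolution order per record: (1) a survey-specific alias —
the mechanism for known protocol corrections such as lumping
hard-to-separate congeners to their genus; (2) exact identifier match;
(3) exact name match after case-folding and whitespace normalization.
Synonyms follow their `accepted_taxon_id` pointer, which the backbone
invariants guarantee lands on an accepted entry in one step. When the
identifier and the name disagree, the identifier wins and the conflict is
logged, since reported codes are less prone to transcription drift than
spellings. There is deliberately no fuzzy matching: approximate matches
need expert eyes, so unmatched names are removed and surfaced in a report
for curation into the alias table rather than silently guessed.

Only the fish classes Elasmobranchii, Holocephali, Chondrostei, Holostei
and Teleostei are retained (macroinvertebrates are not consistently
sampled across surveys); the allowlist is configurable. Records are then
aggregated per (haul, accepted taxon), summing `num` and `wgt` with
absent-aware semantics (the sum is absent only when every part is) and
concatenating the contributing verbatim names as provenance.

## Effort standardization

Swept area uses recorded values when present, then distance × opening,
then duration × speed × opening with the exact conversion 1 kn =
1.852 km/h. Gear opening means wing spread where a survey reports both
wing and door spread, since the wings bound the catching width; a fixed
per-survey opening (as communicated by survey operators) can substitute
for a missing haul-level value. Hauls still lacking an area get
predictions from an ordinary least-squares model fitted per survey on
hauls with known area. Predictors are the largest subset of {duration,
depth, sweep length, country, vessel} each available in ≥ 80% of training
rows — a single model keeps imputations mutually comparable, versus
per-haul best-subset selection; main effects only, categoricals as
indicator contrasts, no interactions or per-vessel slopes. The fit uses
complete cases, requires ≥ 10 rows and more rows than parameters
(otherwise it aborts with advice to use the fixed-opening fallback), and
relies on a pseudoinverse solver so collinear or constant predictors
degrade gracefully without changing predictions. Non-positive predictions
are floored to the smallest observed positive area with a warning; known
areas are never overwritten.

Weights reconstructed from abundance-at-length use `w = a·l^b` with
coefficients in the conventional grams/centimetres calibration, summed
over length-bin midpoints and divided by 1000 to kg. Rates divide the
aggregated catch by duration in hours (CPUE) and by swept area (CPUA); a
rate is absent whenever either side is. The identities `cpua × area = num`
and the speed/distance route sharing one code path are enforced by tests
at 1e-12 relative tolerance and exact equality respectively.

## Temporal taxonomic flags

For each survey unit, the year axis is the set of years the unit sampled
at all, so operational gaps create no artificial transitions. A taxon is
present in a year when any haul recorded a strictly positive `num` or
`wgt`. The flag fires when the presence fraction is below 0.95 *and* the
transition count is below 4, both strict inequalities; both statistics are
reported next to the boolean so users can re-derive alternative rules
(e.g. the disjunction). Units with fewer than two sampled years cannot
support the rule and are skipped with a warning. Flags are advisory: the
package never merges flagged name pairs, which needs survey expertise.

## Footprint flags

**Grid backend.** The hexagonal grid is a regular planar tessellation on a
spherical Lambert azimuthal equal-area projection centred on the midpoint
of the survey unit's coordinate extent, with the per-cell area pinned to
the aperture-3 icosahedral mean `S_earth/(10·3^r + 2)`,
`S_earth = 4π·(6371.0088 km)²`. Surveys are regional, and an equal-area
projection preserves the cell-area semantics of the global icosahedral
grid over such domains without its spherical geometry; the backend is a
small interface (assign / centroid / polygon) so a true discrete global
grid can be swapped in. Tests measure tessellated cells back on the
sphere with an independent spherical-excess oracle and require the mean
to sit within 0.5% of the icosahedral value.

**Core selection.** The ideal of "the largest set of cells and years such
that every retained cell is sampled in every retained year" is the
maximum-complete-submatrix problem, which is NP-hard in general. The
implemented family follows the marginal-coverage ordering under which
well-sampled cells and years collect in one corner of the incidence
matrix: cells sorted by sampled-year count, years by sampled-cell count
(ties lexicographic for determinism), then an exact O(n·m) search over all
top-i × top-j rectangles maximizing i×j subject to the missing cell-year
fraction being within the budget, ties preferring more years, then more
cells. The 2% budget is counted against the retained rectangle (the
scale-free reading; counting against the full matrix is available behind
the same function by adjusting the threshold). Degenerate incidence
patterns built from coverage ties (e.g. permutation matrices) can admit no
rectangle within budget at threshold 0; the selection then returns the
rectangle with the smallest missing fraction under the same tie-breaks,
detectable by `missing_fraction` exceeding the threshold. An exhaustive
brute-force oracle over the same rectangle family verifies the search on
random matrices up to 12×12 at both thresholds.

**BioTIME rule.** The 5×5 grid spans the unit's latitude/longitude extent
(half-open bins, last edge closed, degenerate extents collapse to one
bin). A haul is flagged when its cell-year holds fewer than 4 haul events
("sampled at least 4 times" counts events, not distinct coordinates), and
a whole cell is flagged when fewer than 10 of its years meet that 4-haul
minimum, counting only qualifying years. Ten years is the conventional
minimum series length for temporal ecological analysis.

Every filtered haul carries exactly five booleans; summaries report the
flagged percentage per method per survey unit to one decimal.

## Synthetic surveys and what they show

The generator emulates the integration hazards, not real ecology: no
bathymetry, no gear selectivity, no species interactions, no spatial
autocorrelation of abundance. Defaults define the study conditions used by
the recovery experiments: 20 years; 9 core cells sampled every year and 6
transient cells sampled with 30% yearly probability; 4 hauls per sampled
cell-year (the BioTIME minimum); haul duration Normal(30, 5) minutes
(floored at 10), 4 knots, 20 m opening; an 8-species pool with
Bernoulli-occupancy × lognormal-CPUA catches (`num` = CPUA × true swept
area, kept as a real number, as standardized survey products report); one
planted identification-protocol change, the species-to-genus *Argentina*
switch at the series midpoint. Randomness is a single seed with
deterministically derived sub-streams per stage, so adding a species never
perturbs haul placement and equal seeds give byte-identical tables.

Haul clusters are discs (20 km radius) centred on resolution-7 hexagon
centroids spaced two cells apart. That choice makes each generated cell
coincide with exactly one resolution-7 grid cell, so the footprint
recovery experiment — ≥ 95% of transient-cell hauls flagged, ≤ 5% of
core-cell hauls flagged, pooled over 100 seeds — is asserted for the
resolution-7 / 0%-threshold flag. The resolution-8 lattice has a different
cell size, and a cluster centred on a resolution-7 centroid can legally
straddle a resolution-8 cell edge; resolution-8 flags are therefore tested
for their contracts (completeness, monotonicity, conservation) but not
given a recovery guarantee. Passing recovery shows the flag machinery
identifies planted footprint drift under these conditions; it does not
show how real surveys drift, where cluster geometry is not aligned to any
grid.

## Numerical and degenerate-input choices

Threshold comparisons in core selection use an absolute 1e-9 slack so the
0.02 budget is not lost to floating-point division; at threshold 0 the
integer missing count makes the test exact. Survey tables serialize floats
with the shortest round-tripping representation, so write → read is
bit-for-bit (the default pandas CSV float path is not correctly rounded;
parsing goes through Python's `float`). Empty incidence matrices, empty
presence sequences, non-positive effort values and out-of-range latitudes
raise domain errors rather than propagating NaN. Problem sizes in tests
and in the acceptance script (matrix sizes ≤ 12×12, 100 generator seeds,
10,000-catch identity checks, 100 OLS replicates at n = 1000) were chosen
as the smallest scales at which the checked properties are statistically
meaningful.

## Known limitations

- The sorted-rectangle family is a heuristic restriction of the NP-hard
  ideal; an adversarial incidence matrix can have a larger unordered
  complete submatrix than any ordered rectangle.
- The planar hexagonal backend tiles a regional projection plane; it is
  not a global discrete grid, and cell identities are not comparable
  across survey units.
- Harmonization is exact-match only by design; heavily misspelled source
  names require curation through the alias table.
- The generator's lognormal catch model has no zero-inflation beyond
  Bernoulli occupancy and no temporal trend; taxon-flag performance on
  genuinely trending or collapsing populations is not characterized here.
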