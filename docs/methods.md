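# Methods

## The delimitation problem

*Plectostoma* snails are obligate inhabitants of limestone outcrops that sit
like islands in a non-limestone matrix. Populations on different hills have
plausibly been isolated for millions of years, so mitochondrial lineages are
deeply structured even within uncontroversial species. Tree-based
delimitation (GMYC-style "every deep lineage is a species") would therefore
oversplit, and interbreeding criteria are untestable. The workflow
implemented here instead triangulates three data types — shell characters,
hill-level co-occurrence, and COI barcode divergences — with explicit,
auditable decision rules.

## Morphology

A species is scored on 11 qualitative shell characters, each cell a *set* of
integer state codes: singleton for fixed characters, multi-valued for
polymorphism (the literal `a or b` dialect in the source table), empty for
unknown (`?`). Two equality semantics are implemented:

- **exact** (default): profiles are equal iff every cell's state set is
  identical, with `?` equal only to `?`. This is the semantics under which
  the packaged matrix yields 27 unique species of 31 with exactly two
  shared-profile pairs.
- **overlap** (optional flag): species are grouped by the transitive closure
  of "no character has disjoint known states". More conservative; groups
  species whose polymorphic ranges merely intersect.

Diagnostic characters for a species pair are those with disjoint, known
state sets; unknown cells are never diagnostic. Form rows (infrasubspecific
samples scored separately) are collapsed by state-set union per character —
a merged cell is unknown only if all forms are unknown. Union is the
conservative choice: it never manufactures a diagnostic difference that some
form does not show.

Species descriptions carry the quantitative fields (spire height/width in
mm, whorl counts, rib density per mm, tuba length and attachment fractions,
whorl-periphery convexity) with genus-wide plausibility bounds enforced at
load time (spire height 1.0–3.8 mm, width 0.85–2.60 mm, rib density 3–32
per mm).

## The identification key

The printed 30-couplet key is stored verbatim; a curated annotation layer
attaches machine predicates to each lead — in-set predicates on matrix state
codes, inclusive numeric ranges on description fields (e.g. "Spire 1.6–1.9
mm high"), and token-set predicates for qualitative description terms. Three
terminals (P. klongsangensis, P. kitteli, P. tonkinianum) lie outside
Peninsular Malaysia but are retained; the key covers all 31 revised species.

Traversal is deterministic: at each couplet exactly one lead must evaluate
true. A categorical subject state is matched by subset (a polymorphic
`{2,3}` satisfies a lead demanding `{2,3}` but neither `{2}` nor `{3}`
alone); numeric subject ranges must fall entirely inside a lead's interval,
and interval predicates are inclusive at both ends. A value falling in both
leads' ranges raises an ambiguity error rather than silently choosing; a
missing value raises an incomplete-subject error naming the couplet. The
consistency check runs every species' own coded data through the key and
*reports* conflicts with provenance. On the packaged data exactly one
conflict appears: *P. annandalei*'s whorl periphery is described as
moderately convex while couplet 26 separates on "distinctly" vs "slightly"
convex — a genuine gap in the source key that the check surfaces and, by
design, does not resolve.

Intensity terms in apex-related leads map to the matrix legend as
distinctly/moderately/slightly convex = codes 1/2/3; leads using periphery
terms absent from the legend are encoded as description-field predicates.

## Barcode divergence

- **Site-coverage filter.** A column is kept iff the fraction of unambiguous
  A/C/G/T residues is ≥ c (default 0.95). The filter is idempotent and
  precedes all distance computation; residual per-pair ambiguities are then
  deleted pairwise, which keeps the per-pair L explicit.
- **K2P distance.** d = −½ ln[(1−2P−Q)√(1−2Q)] with P = s/L, Q = v/L.
  Saturation (non-positive log argument) raises an explicit signal; the
  distance matrix stores NaN and every aggregate touching such a pair is
  marked *undetermined* with a reason, never silently propagated.
- **Aggregation.** Within-group divergence is the arithmetic mean over all
  intra-group pairs (undefined for singletons); net between-group divergence
  subtracts the average of the two within means, treating a singleton's
  within as 0 so pairs involving singletons stay defined — this matches how
  the reference table prints between-values for singleton species.
- **Threshold screen.** τ = 0.10 by default, configurable. Lump candidacy is
  strict (net < τ); a pair exactly at τ is distinct but annotated
  *borderline*. Split candidacy is within ≥ τ. The published fauna uses
  "below 9%" as the observed within-species ceiling but 10% as the decision
  threshold; both screens default to 10% here, and τ is a parameter where a
  user wants the stricter reading.
- All codon positions are used; there is no codon partitioning, matching the
  barcode analysis the table documents.

Reported divergences in the packaged table are printed at 2 decimals; the
screen operates on those printed values for fixture-derived results, while
internal arithmetic on computed matrices is full precision.

### Note on the packaged divergence table

One typeset cell of the source table (tohchinyawi × salpidomon) prints 0.06
in some renderings, which contradicts the table's own convention (sub-10%
distances are bolded, and only the two crassipupa cells are bold), the
stated count of 169 pairs above threshold, and the absence of any discussion
of such a striking anomaly. The packaged fixture records 0.16, the minimal
single-digit emendation consistent with all three. The printed within-species
SD of 0.1% is likewise not reproducible from the printed values
(recomputation gives ≈ 3.8%) and is not a target of any check here.

## Reciprocal illumination

Rules run in the order R1 → R2 → R3 → R4 (configurable; the default
reproduces the published decisions). The source narrative checks sympatry
first, genetics second, and morphology as tiebreaker, but states no formal
order — fixing one makes the procedure deterministic and the trails
reproducible. Merge targets default to the alphabetically first name; a
priority map can encode nomenclatural priority instead. Groups without
barcode data pass through on morphology alone, confirmed with a note (the
treatment the revision gives to species like *P. annandalei*). "Same hill"
is 3-decimal coordinate equality because records are georeferenced to the
hill centroid, not the collecting spot; note that a few distinct named hills
in the records share rounded coordinates — locality text is retained so
downstream users can exclude them.

## Collection records and KML

Shell counts below 10 are stored exactly; larger samples use the four coarse
categories whose parenthetical ranges are authoritative (the labels
themselves are self-contradictory): ">10" = 10–24, ">25" = 25–49, ">50" =
50–100, ">100" = 101+. Distances use the haversine formula on the WGS84
mean-radius sphere (6371.0088 km) — adequate for tens-of-km hill spacing.
Dates parse leniently (year-only allowed); unparseable dates are stored
verbatim with a flag. KML output is OGC KML 2.2 via lxml: folder name =
species, placemark name = collection reference, title (species + reference)
and the collection-data paragraph in each placemark, coordinates in lon,lat
order.

## Synthetic data

The sequence simulator draws a uniform-composition root and evolves each
site independently under the K80 process using the model's *exact* site
transition functions at the target depth (no small-step discretisation), so
the expected K2P distance of a simulated pair equals the nominal depth
analytically. The clade panel is a star phylogeny — species ancestors at
d_b/2 from the root, specimens at a further d_w/2 — which is the minimal
structure matching the within/net summaries of hill-isolated allopatric
populations: within-species pairs have expectation d_w, cross-species pairs
d_b + d_w, and the net between-group divergence is d_b by construction.
Defaults are kappa = 2, L = 615 (the length of the filtered barcode
alignment), d_w = 0.02 and d_b = 0.15, i.e. comfortably astride the 10%
threshold, matching the observed fauna. A sampled coalescent, rate
heterogeneity, indels and selection are deliberately out of scope.

Matrix simulation plants exact duplicate-profile pairs and injects
polymorphism and missing states identically within a planted pair; the
planted structure is verified after injection and re-drawn if broken (at
missing_rate = 1 the matrix degenerates to all-unknown and no structure is
enforced). Key construction is greedy-balanced: at each node the
(character, state-subset) split minimising the larger partition wins, ties
broken by character order then subset; it requires all species at a node to
have known states for the splitting character, so a built key never routes
through an unknown. Simulated records plant sympatry by assigning species to
shared sites whose rounded coordinates are guaranteed distinct across sites.

What passing the synthetic tests does **not** show: the simulators assume
equal base frequencies, no rate variation among sites, and a star topology,
so they validate estimator algebra and pipeline plumbing, not robustness to
compositional bias, rate heterogeneity, or non-star histories in real data.

## Numerical and design notes

- Estimator calibration uses 100 replicate pairs per depth at L = 10,000
  (absolute bias < 0.005 at depths 0.05/0.10/0.20); the end-to-end recovery
  check uses 5 species × 3 specimens at L = 2,000, sizes at which the whole
  suite runs in seconds.
- Distance-matrix symmetry, non-negativity and zero diagonal are enforced at
  construction; group aggregation is cross-checked in the tests against an
  exhaustive pair-enumeration oracle, and the K2P matrix against an
  independent R implementation (ape's K80 distance with pairwise deletion).
- Profile grouping uses union-find; under exact semantics equality is
  already transitive, under overlap semantics the closure is intended.
- Ties in the greedy key builder and all report orderings are broken
  deterministically (character order, lexicographic names), so identical
  inputs give byte-identical outputs.

## Limitations

- The key's machine predicates are a curated layer: leads mixing several
  observations were encoded as conjunctions, and two couplets rest on
  description fields (peristome projection, tuba visibility in top view)
  that are coarse categories, not measurements.
- Net divergence with singleton groups understates the correction (within
  treated as 0), exactly as in the reference table.
- The delimitation rules operationalise a narrative procedure; R1–R4 cover
  the published cases but are not a general-purpose species concept.
- Coordinates are hill centroids; sympatry below the ~100 m rounding scale
  and parapatry on large hills are invisible to the pipeline.
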