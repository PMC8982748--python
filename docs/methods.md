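# Methods

## Problem and model

When a patient is referred to a specialty department, their outside
medical records (OMRs) typically arrive as scanned faxes. After OCR and
concept extraction, each corpus becomes a set of *concepts*: triples
`(normalized term, semantic group, patient id)`, rendered
`term::GROUP::patient`. Three corpus-level sets are compared:

* `C_OMR` — concepts extracted from the outside records;
* `C_ICN` — concepts from the consultant notes written on the patient's
  initial encounter (the first in-house note strictly after the latest
  date resolvable from the OMR metadata);
* `C_FCN` — concepts from consultant notes written 1–90 days after the
  initial encounter.

The three sets decompose into the seven disjoint Venn regions A–G
(A = in all three, B = OMR∩ICN only, C = OMR∩FCN only, D = ICN∩FCN only,
E = ICN only, F = FCN only, G = OMR only). Region B, for example, is
information from the outside records that was used at the initial
encounter but dropped in follow-up; region G is outside-record
information never incorporated in-house.

Two overlap statistics are computed against `C_CN = C_ICN ∪ C_FCN`:

* exact intersection ratio `r_e = |C_OMR ∩ C_CN| / |C_CN|`;
* flexible intersection ratio `r_s = |C_SIMILAR| / |C_CN|`, where
  `C_SIMILAR` holds, for each OMR concept, the CN concept with the
  highest terminology path similarity `sim(c_i, c_j) = 1 / l(c_i, c_j)`
  (`l` = node count of the shortest is-a path, endpoints included;
  identical concepts give 1, unmappable or disconnected pairs give the
  sentinel −1, so scores lie in (0, 1] ∪ {−1}).

Concept *saliency* for a specialty is the concept's mention frequency in
the specialty's notes divided by its frequency across all practice
settings of a large background corpus; 1 means specialty-exclusive. The
region-level average divides the region's score sum by the number of
concepts with strictly positive scores; because that denominator
convention is not the only defensible one, the report also emits the
variant that divides by all background-mapped concepts.

## Key conventions and their rationale

* **Concept identity includes the patient id.** Unions and region
  algebra therefore never collide across patients. Saliency is the one
  population-level statistic; it projects each key to its
  `(term, group)` pair explicitly at lookup time.
* **Experiencer filter.** Only mentions whose experiencer is the patient
  enter any statistic; family-history mentions ("his father had a heart
  attack") are excluded. Assertion and temporality attributes are
  carried through I/O but never interpreted.
* **Semantic groups.** A single mention tagged with a compound group
  (e.g. `CHEM;DRUG`) is one concept with the joint, canonically sorted
  group; the same term tagged differently in different mentions (`CT` as
  FIND and as PROC) yields distinct concepts.
* **Follow-up window.** "1 to 90 days after the initial encounter" is
  exactly the half-open day window (initial, initial + 90]; day 90 is in,
  day 91 is out. The initial encounter itself must fall *strictly* after
  the reference date. Both choices follow the day-level wording rather
  than the looser "3 months".
* **Flexible-match tie-breaks.** Identical normalized terms count as
  identical concepts (similarity 1.0) even when the toy terminology has
  no entry for them — a terminology gap should not make an exact string
  match look unrelated. Among tied candidates, an OMR key that itself
  exists in CN claims its own twin; remaining ties go to the
  lexicographically smallest rendered key. Together these make
  `r_s ≥ r_e` hold at every threshold below 1, which is also asserted as
  a property test. `|C_SIMILAR|` counts distinct *CN* concepts, so
  `r_s ≤ 1` always.
* **Match threshold.** Default 0: any mapped, connected pair qualifies
  (the sentinel −1 never passes). Configurable because reasonable
  analyses may want to exclude weak paths; at thresholds ≥ 0.5 the
  one-edge-away matches disappear and `r_s` collapses to `r_e`.
* **Rounding.** Table percentages are exact-rational division rendered
  half-up at 2 decimals (`decimal.Decimal`, not float rounding);
  saliency averages at 3 decimals.

## Synthetic corpora

Real referral corpora are private patient records, so the generator
plants the structure the pipeline must recover:

* **Region cardinalities are exact, not sampled.** Each region's concept
  count is planted globally and dealt round-robin across patients; a
  concept's region determines exactly which corpora mention it. The
  generator's defaults are the reference study's conditions: 294
  patients, regions (A..G) = (4,793; 14,371; 6,745; 6,050; 34,947;
  23,660; 141,013) — giving |C_OMR| = 166,922, |C_ICN| = 60,161,
  |C_FCN| = 41,248, 231,579 unique concepts — with the published
  per-semantic-group frequencies planted in regions A–C (the residual
  between the six major published rows and the region totals is spread
  over CHEM/ACTI/CONC by largest remainder at fixed 0.6/0.2/0.2
  proportions).
* **Dates** exercise the corpus-assignment machinery by construction:
  one reference date per patient (expert metadata for 80% of patients,
  PDF-creation fallback for the rest), initial encounter 7 days later,
  follow-up notes scattered over days 1–90 including the day-90
  boundary, a pre-reference in-house note for 10% of patients (its
  mentions duplicate already-planted concepts, so mis-handling it would
  change the logged drop counts but not silently corrupt sets).
* **Noise that must be filtered.** ~5% extra mentions carry experiencer
  "Others" with terms disjoint from every planted set — if the filter
  were skipped, the recovered cardinalities would change.
* **Terminology and near matches.** A random is-a tree (default 500
  concepts, with synonym surface terms for 10% of them). A configurable
  fraction (default 10%) of OMR-only concepts is planted one edge away
  from a note-corpus concept: the tree's first nodes form a caterpillar
  whose pendant edges are vertex-disjoint, each pendant carrying one
  OMR-only term and its interior neighbour the CN counterpart term. Each
  planted pair therefore contributes exactly one similarity-0.5 match
  and `|C_SIMILAR|` grows by exactly the number of planted pairs.
* **Background frequency profile.** Per region, the number of concepts
  present in the background corpus is planted deterministically as
  `round(rate × region size)` with the study's per-region mapping rates
  as defaults, and per-region saliency score sums are planted exactly at
  a common all-practice denominator of 10⁶ mentions (per-concept scores
  vary by ±50% around the region mean; the largest count absorbs the
  rounding residue). Planted specialty-exclusive concepts (default 25,
  drawn from region E) get equal specialty and overall counts, hence
  score exactly 1.
* Identical seeds produce byte-identical files; all randomness flows
  from `numpy` generators seeded from the single spec seed.

**What passing tests do and do not show.** The generator reproduces the
set-level and frequency-level *structure* of referral corpora, not their
content: terms are synthetic labels, the terminology is a random tree
rather than a curated vocabulary, mention counts are Poisson-ish rather
than burst-distributed, and OCR/NER noise (mis-recognized terms, missed
mentions) is absent. Recovering planted cardinalities therefore
validates the pipeline's bookkeeping and arithmetic, and says nothing
about NER quality on real notes; the flexible-match percentages
achievable on real data depend entirely on the richness of the real
terminology and are not emulated.

## Numerical and scale choices

* The full default-scale run (≈231K unique concepts, ≈338K mention
  records) generates in ~6 s and analyses in ~11 s; tests use corpora of
  tens of concepts. Pairwise flexible matching is reserved for the small
  planted fixtures: it shares one breadth-first sweep per distinct OMR
  term, but a corpus-scale toy terminology would make the quadratic
  term-pair space pointless to grind through, and the flexible
  percentages would reflect the random tree rather than anything
  meaningful.
* Degenerate inputs: an empty CN corpus makes both ratios undefined
  (raised, not NaN); a region with no positively scored concepts reports
  average 0 with an explicit flag; an empty overlap yields an empty
  coverage table.
* Unparseable dates in annotation files become absent dates rather than
  errors (scanned-document pages routinely lack dates); patients whose
  reference date or initial encounter cannot be resolved are dropped and
  counted in the run report.

## Known limitations

* The toy terminology has one concept per surface term; word-sense
  ambiguity and richer relation types are out of scope.
* Saliency uses raw frequency ratios with no smoothing, so rare
  background concepts can score 1 spuriously on real data (on synthetic
  data exclusives are planted and exact).
* The section distribution counts distinct (concept, section) pairs;
  it does not model section-to-section information drift over time.
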