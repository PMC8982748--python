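# omrlap

Concept-overlap and specialty-saliency analysis between **outside
medical records** (OMRs — the scanned faxes that accompany a referred
patient) and the receiving institution's own **EHR consultant notes**.

Referral centers receive large volumes of scanned outside records whose
content may or may not be incorporated into in-house care. Given concept
annotations extracted by an NLP engine (one row per concept mention,
with patient, document, date, note section, normalized term, semantic
group and experiencer), `omrlap` quantifies how that information flows:

* splits in-house consultant notes into **initial-encounter notes
  (ICN)** and **1–90-day follow-up notes (FCN)** by resolving each
  patient's reference date from OMR metadata;
* builds per-corpus concept sets keyed `term::SEMGROUP::patient` and
  partitions `C_OMR`, `C_ICN`, `C_FCN` into the seven disjoint Venn
  regions A–G (A = in all three corpora, …, G = outside-record
  information never used in-house);
* computes the exact intersection ratio `r_e = |C_OMR ∩ C_CN| / |C_CN|`
  and the flexible ratio `r_s = |C_SIMILAR| / |C_CN|`, where
  `C_SIMILAR` collects each OMR concept's best terminology match under
  the path measure `sim(c_i, c_j) = 1 / l(c_i, c_j)` (`l` = node count
  of the shortest is-a path; unmappable pairs score −1);
* tabulates overlap coverage by semantic group and by note section;
* scores each concept's **specialty saliency** — its mention frequency
  in the specialty's notes divided by its frequency across all practice
  settings of a background corpus (1 = specialty-exclusive) — and
  aggregates sums, averages and top-ranked concepts per region.

Because real referral corpora are private, the package includes a
first-class synthetic generator that plants region cardinalities,
semantic-group tables, date structure, terminology near-matches and
background frequencies exactly, so every statistic the pipeline reports
has a known ground truth. Audience: clinical-NLP and medical-informatics
researchers studying information continuity across care transitions.

## Worked example

Generate a small fixture (20 patients, region cardinalities scaled to
0.1% of the defaults) and run the whole pipeline:

```sh
omrlap generate --seed 42 --n-patients 20 --scale 0.001 --out demo/fixture
omrlap all \
  --annotations demo/fixture/annotations.tsv \
  --metadata    demo/fixture/metadata.tsv \
  --terminology demo/fixture/terminology.tsv \
  --background  demo/fixture/background.tsv \
  --output-dir  demo/out
```

which prints (abridged):

```
== Corpus sizes ==
         C_OMR: 167
         C_ICN: 60
         C_FCN: 42
          C_CN: 91
  total_unique: 232

== Region cardinalities (Venn A..G) ==
             A: 5
             B: 14
             C: 7
             D: 6
             E: 35
             F: 24
             G: 141

== Intersection ratios ==
              exact_ratio_cn: 28.57%
             exact_ratio_icn: 31.67%
           flexible_ratio_cn: 43.96%
        icn_share_of_overlap: 73.08%
     overlap_of_total_unique: 11.21%
   region_B_share_of_overlap: 53.85%
   ...
```

Reading this: 11.21% of all 232 unique concepts occur in both the
outside records and the in-house notes; of those overlapping concepts,
73.08% already appear in the initial-encounter notes, and region B
(used initially, dropped in follow-up) is the largest overlap cell at
53.85%. The exact ratio against the combined note corpus is 28.57%;
terminology near-matches planted one is-a edge away raise the flexible
ratio to 43.96%. Region cardinalities equal the planted ground truth
exactly. The run also writes `summary.json`, a semantic-group coverage
table and the full text report under `demo/out/`.

The same analysis is available as a library:

```python
from omrlap import SyntheticSpec, generate_corpora, RunConfig, run_pipeline

gen = generate_corpora(SyntheticSpec(seed=1), "scratch/fixture")
summary = run_pipeline(RunConfig(
    annotations=gen.paths["annotations"], metadata=gen.paths["metadata"],
    terminology=gen.paths["terminology"], background=gen.paths["background"],
))
print(summary.region_cardinalities)   # {'A': 4793, 'B': 14371, ...}
```

See `docs/methods.md` for the model, the conventions (tie-breaks,
rounding, the 90-day window) and what the synthetic corpora do and do
not emulate.

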