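# Methods

## Problem and approach

Spirometry results in many health systems exist only inside clinical
notes. Where a facility reports PFTs with a consistent syntactical
template, a small amount of facility-specific configuration — an anchor
phrase plus a handful of regular expressions — recovers the quantitative
values far more precisely than generic NLP. `pftmine` turns that
observation into a data-driven pipeline: facility behaviour lives in a
template registry (YAML), not in code branches, and everything downstream
of the registry is generic.

The pipeline classifies each PFT study on two axes:

- **Obstruction**: FEV1/FVC < 0.70, strict inequality, on the fraction
  scale. A ratio printed as a percent (e.g. "65%") is divided by 100 when
  it falls in (1, 120]; larger values are implausible and dropped.
- **Severity of FEV1 impairment** (percent predicted): normal [80, ∞),
  mild [70, 80), moderate [60, 70), moderately severe [50, 60), severe
  [35, 50), very severe (0, 35). The guideline ranges are printed as
  integer bands ("70–79%"); we realise them as half-open real intervals
  so that non-integer percents (79.5) classify deterministically, and the
  integer ranges are recovered exactly at integers.

Quantitative values always take priority; qualitative descriptors are
used only when the number is absent. A quantitative-vs-qualitative
conflict is logged as a discordance event for audit but never changes the
call. When severity has neither a percent-predicted value nor an FEV1
descriptor but the obstruction descriptor itself carries a grade
("severe obstruction"), that grade supplies the severity band; a bare
"obstruction" with no severity word yields obstruction present with
severity missing.

## Cohort and linkage parameters

| parameter | default | meaning |
|---|---|---|
| CPT codes | 94010, 94375, 94060, 94726, 94727, 94729, 94150 | spirometry and related PFT procedure codes |
| note window | [−1, +21] days | note eligibility relative to procedure date, endpoints inclusive |
| top-N facilities | 36 | volume screen before coverage screen |
| FEV1-note coverage | ≥ 0.80 | facility eligibility threshold |
| obstruction threshold | 0.70 | fixed-ratio criterion (strict <) |
| snippet window | 150 before / 1000 after | characters around the anchor phrase |

The coverage comparator is configurable (`>=` vs `>`); we adopt `>=`
because 8 FEV1-covered studies out of 10 should count as reaching an 80%
threshold. "FEV1-containing" is matched by the tolerant pattern
`FEV[\s-]?1`, case-insensitive, since reports also print "FEV-1" and
"FEV 1".

The snippet's "before" span is measured from the anchor match start and
the "after" span from the match end, so the anchor is always fully inside
the window. Only the first anchor match per note produces a snippet, and
only the first matching note per study is used: multiple studies listed
sequentially in one note are not partitioned (a known limitation of the
window approach).

## Extraction details

- **Pre-bronchodilator restriction.** Before any pattern runs, segments
  opened by a post-bronchodilator marker (`post[\s-]?(bronchodilator|bd|drug)`)
  are blanked with spaces up to the next pre-bronchodilator marker, blank
  line, or end of snippet. Blanking preserves length, so every provenance
  offset indexes the original snippet.
- **First match wins** within each slot (FEV1 liters, FEV1 percent
  predicted, ratio): single per-study values in reading order are the
  reproducible choice.
- **Number parsing** strips comma thousands separators and an optional
  trailing "%".
- **Plausibility ranges** (configurable): liters (0.2, 10), percent
  predicted (5, 200), normalised ratio fraction (0.1, 1.5). These reject
  page numbers, dates and list indices captured by loose patterns; a
  dropped value is logged, never silently kept.
- **Qualitative lexicon** is shipped data (`data/lexicon.yaml`): ordered
  (pattern, field, category) entries with negation entries mapping to
  "no obstruction". Disambiguation is by span containment (a match inside
  a longer match is discarded — so "moderately severe obstruction" beats
  the contained "severe obstruction", and a negated phrase suppresses the
  bare descriptor inside it), then by distance to the anchor.

## Synthetic corpus

The generator emulates what matters for exercising the pipeline:
facility-to-facility dialect variation (three shipped dialects: a
colon-delimited block style, an equals-sign report style, and a narrative
style that prints the ratio as a fraction), qualitative-only reporting,
post-bronchodilator blocks with different values, distractor notes that
mention FEV1 in prose without any results template, and missing values.
Per-study defaults:

- obstruction prevalence 0.707; true ratios uniform on [0.400, 0.699]
  (obstructed) or [0.700, 0.900] (not), rounded to 3 decimals so that the
  percent rendering used by two dialects is exact;
- severity-band weights proportional to 4535 / 3397 / 3663 / 3270 / 5547
  / 3317 with 1193 missing (the marginals of the reference
  cross-tabulation); percent predicted drawn uniformly at integers within
  the band (normal capped at 120, very severe floored at 15);
- 10% qualitative-only notes, 30% with a post-bronchodilator block, 5%
  distractors, 5% missing-ratio values. These rates are chosen to make
  every fallback path common enough to be exercised by a moderate corpus
  while keeping templated quantitative notes the dominant kind, as in
  real report streams.

Obstruction and severity are drawn independently (only the marginals are
specified), so the generator does not reproduce the physiological
correlation between a low ratio and a low FEV1; that correlation is
irrelevant to extraction testing. FEV1 in liters is a decorative derived
value (3.5 L reference × percent/100). Identifiers are synthetic tokens;
no demographic realism is attempted.

Ground truth is derived by building, for each note, the idealised
extraction containing exactly the values the note renders, and running it
through the same classification criteria. This guarantees internal
consistency (the stored label always equals the rule applied to the
drawn values — independently re-checked in the tests) and defines
recovery sharply: on a clean corpus, any disagreement between pipeline
output and truth is a pipeline defect, not generator noise.

What passing therefore shows: the window/mask/extract/classify chain is
exact on well-formed templated notes in the shipped dialects, robust to
the perturbation classes the dialect patterns are written to tolerate
(whitespace jitter, "FEV1/FVC"↔"FEV1:FVC", comma grouping, percent-sign
dropout), and correct in its fallback routing. What it does not show:
yield or accuracy on real clinical notes, whose dialect drift, OCR
artefacts and multi-study snippets are outside the generator's model.

## Numerical and design choices

- Dates are whole calendar days (ISO-8601); the linkage window needs no
  time-of-day.
- Notes are kept byte-faithful; normalisation (NFC, CR/LF→LF, NBSP→space)
  happens once, in the snippet extractor, and all offsets refer to the
  normalised text. Offsets are 0-based, half-open.
- Headline percentages are rounded half-away-from-zero to one decimal,
  which makes printed values stable and exactly reproducible.
- Missing output values are empty CSV cells, never a sentinel string.
- Facility ranking ties break lexicographically; registry duplicate
  facility entries are a hard load error (silent override is an audit
  hazard).
- Agreement validation counts missing-predicted vs missing-truth as a
  match: correctly determining that a value is absent is itself a correct
  determination. Sampling is simple random without replacement, seeded,
  over sorted study ids, so record order never matters.

## Problem sizes

The acceptance computation replays the 24,922-record reference
cross-tabulation and runs a 2,004-study synthetic corpus (6 facilities ×
334 notes) twice (clean and perturbed), with a 100-study validation
sample; this is ample to exercise every code path and classification
band while completing in seconds.

## Known limitations

- One snippet per study: sequential studies inside one window are not
  separated.
- The fixed 0.70 ratio criterion and 2005 ATS/ERS bands only; no
  lower-limit-of-normal or z-score interpretation (the threshold value is
  configurable, the interpretation model is not).
- No extraction of FVC in liters, DLCO, lung volumes, or bronchodilator
  response.
- Shipped dialects are synthetic reconstructions; applying the pipeline
  to a real facility requires authoring its template entry.
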