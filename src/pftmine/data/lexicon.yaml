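# Qualitative descriptor lexicon.
#
# Ordered list of (pattern, field, category) entries mapping descriptor
# phrases in PFT interpretations to the enumerated categories.  Patterns
# are compiled case-insensitively.  Entries with `negation: true` express
# absence of obstruction.
#
# Disambiguation is by span containment: a match whose span lies inside a
# longer match's span is discarded, so "no evidence of obstruction" beats
# the bare "obstruction" it contains, and "moderately severe obstruction"
# beats the "severe obstruction" it contains.

entries:
  # --- obstruction descriptors -------------------------------------------
  - pattern: 'no\s+(?:evidence\s+of\s+|significant\s+)?(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: no_obstruction
    negation: true
  - pattern: 'without\s+(?:evidence\s+of\s+)?(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: no_obstruction
    negation: true
  - pattern: 'normal\s+spirometry'
    field: obstruction
    category: no_obstruction
    negation: true
  - pattern: 'very\s+severe\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: very_severe
  - pattern: 'moderately[\s-](?:severe|to[\s-]severe)\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: moderately_severe
  - pattern: 'moderate[\s-]to[\s-]severe\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: moderately_severe
  - pattern: 'severe\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: severe
  - pattern: 'moderate\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: moderate
  - pattern: 'mild\s+(?:airflow\s+)?obstruct\w+'
    field: obstruction
    category: mild
  - pattern: 'obstruct(?:ion|ive|ed)\w*'
    field: obstruction
    category: unspecified_obstruction

  # --- FEV1 severity descriptors -----------------------------------------
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+normal'
    field: fev1
    category: normal
  - pattern: 'normal\s+FEV[\s-]?1'
    field: fev1
    category: normal
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+mildly\s+(?:reduced|decreased)'
    field: fev1
    category: mild
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+moderately\s+(?:reduced|decreased)'
    field: fev1
    category: moderate
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+moderately[\s-]severely\s+(?:reduced|decreased)'
    field: fev1
    category: moderately_severe
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+severely\s+(?:reduced|decreased)'
    field: fev1
    category: severe
  - pattern: 'FEV[\s-]?1\s+(?:is|was)\s+very\s+severely\s+(?:reduced|decreased)'
    field: fev1
    category: very_severe
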