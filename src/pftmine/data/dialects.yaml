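# Synthetic PFT report dialects.
#
# These three dialects are plausible reconstructions of templated
# pulmonary-function-report styles used for testing; they are NOT
# transcriptions of any real facility's notes.  Each dialect defines the
# anchor phrase that opens the results block, the snippet window, and the
# extraction patterns for the four slots.
#
# Pattern notes:
#   - all patterns are compiled case-insensitively
#   - numbers are captured as (\d+(?:[.,]\d+)*) so a trailing sentence
#     period is never swallowed
#   - the "%" sign is always optional so percent-sign dropout is harmless
#   - "FEV1/FVC" and "FEV1:FVC" are both accepted via [/:]

dialects:
  riverside:
    anchor_pattern: 'SPIROMETRY\s+RESULTS'
    before_chars: 150
    after_chars: 1000
    dialect_patterns:
      fev1_liters: 'FEV[\s-]?1:\s*(\d+(?:[.,]\d+)*)\s*L\b'
      fev1_pct_pred: '\(\s*(\d+(?:[.,]\d+)*)\s*%?\s*predicted\s*\)'
      ratio: 'FEV[\s-]?1\s*[/:]\s*FVC:?\s*(\d+(?:[.,]\d+)*)\s*%?'
      qualitative_section: 'Interpretation:[^\n]*'

  lakeview:
    anchor_pattern: 'PULMONARY\s+FUNCTION\s+TEST\s+REPORT'
    before_chars: 150
    after_chars: 1000
    dialect_patterns:
      fev1_liters: 'FEV[\s-]?1\s*=\s*(\d+(?:[.,]\d+)*)'
      fev1_pct_pred: '\(\s*(\d+(?:[.,]\d+)*)\s*%?\s*pred(?:icted)?\s*\)'
      ratio: 'FEV[\s-]?1\s*[/:]\s*FVC\s*[=:]?\s*(\d+(?:[.,]\d+)*)\s*%?'
      qualitative_section: 'IMPRESSION:[^\n]*'

  summit:
    anchor_pattern: 'Pulmonary\s+Function\s+Interpretation'
    before_chars: 150
    after_chars: 1000
    dialect_patterns:
      fev1_liters: 'FEV[\s-]?1\s+(\d+(?:[.,]\d+)*)\s*L\b'
      fev1_pct_pred: '(\d+(?:[.,]\d+)*)\s*(?:%|percent)\s+of\s+predicted'
      ratio: 'FEV[\s-]?1\s*[/:]\s*FVC\s*(?:ratio)?\s*[=:]?\s*(\d+(?:[.,]\d+)*)\s*%?'
      qualitative_section: 'Impression:[^\n]*'
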