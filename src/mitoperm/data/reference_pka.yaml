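# Reference-anchored pKa predictions for TPP carboxylic acids.  Each column
# of `predictions` is anchored to one reference acid with an experimentally
# known pKa; the self-anchored entries reproduce the experimental value by
# construction.  summaries_printed gives the published mean +- half-range
# over the two references.
schema: mitoperm-reference-pka/1
references:
  PhCOOH:
    pka_experimental: 4.204
  PhCH2COOH:
    pka_experimental: 4.31
predictions:
  PhCOOH:
    PhCOOH: 4.204
    PhCH2COOH: 4.4
  PhCH2COOH:
    PhCOOH: 4.1
    PhCH2COOH: 4.31
  TPMP+-COOH:
    PhCOOH: 2.4
    PhCH2COOH: 2.6
  TPMP+-CH2COOH:
    PhCOOH: 2.6
    PhCH2COOH: 2.8
  TPMP+-CH2CH2COOH:
    PhCOOH: 5.1
    PhCH2COOH: 5.3
summaries_printed:
  TPMP+-COOH:
    mean: 2.5
    half_range: 0.1
  TPMP+-CH2COOH:
    mean: 2.7
    half_range: 0.1
  TPMP+-CH2CH2COOH:
    mean: 5.2
    half_range: 0.1
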