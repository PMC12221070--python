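# Small synonym resource for lexicon expansion (term -> synonyms).
# Stands in for a full lexical database; any mapping with this layout works.
synonyms:
  unemployed: [jobless, out of work]
  jobless: [unemployed]
  insured: [covered]
  uninsured: [without insurance]
  homeless: [unhoused, houseless]
  elderly: [aged, geriatric]
  severe: [grave, serious]
  mild: [slight]
  married: [wedded]
  single: [unattached]
  isolated: [lonely, solitary]
  sober: [abstinent]
  disabled: [handicapped]
  wealthy: [affluent, rich]
  poor: [impoverished, destitute]
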