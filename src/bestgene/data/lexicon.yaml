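# Direction lexicon for the bidirectional screen.
#
# Each axis is a quantitative phenotype; up_terms / down_terms are phrases
# (matched whole, case- and punctuation-insensitively) that indicate a
# disease label pushes the axis up or down.  Labels containing an exclusion
# phrase are molecular/cellular/benign phenotypes and are never classified.
axes:
  stature:
    up_terms:
      - tall stature
      - overgrowth
      - gigantism
    down_terms:
      - short stature
      - dwarfism
      - idiopathic short stature
  LDL cholesterol:
    up_terms:
      - high ldl cholesterol
      - hypercholesterolemia
    down_terms:
      - low ldl cholesterol
      - hypocholesterolemia
  QT interval:
    up_terms:
      - long qt syndrome
    down_terms:
      - short qt syndrome
  blood glucose:
    up_terms:
      - hyperglycemia
      - high blood glucose
    down_terms:
      - hypoglycemia
      - low blood glucose
  coagulation:
    up_terms:
      - thrombophilia
      - hypercoagulability
    down_terms:
      - bleeding diathesis
      - hemophilia
  thyroid hormone:
    up_terms:
      - hyperthyroidism
    down_terms:
      - hypothyroidism
  blood pressure:
    up_terms:
      - hypertension
      - high blood pressure
    down_terms:
      - hypotension
      - low blood pressure
  hemoglobin:
    up_terms:
      - erythrocytosis
      - polycythemia
    down_terms:
      - anemia
exclusions:
  - enzyme activity
  - cell permeability
  - pigmentation
  - protein expression
  - membrane potential
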