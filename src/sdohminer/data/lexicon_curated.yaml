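# Curated entity-variation dictionary: per-type surface-form variants used
# to fill template slots.  Illustrative and deliberately small; a larger
# externally generated dictionary can be dropped in with the same layout.
entries:
  Access_To_Care:
    - "clinic visit"
    - "hospital admission"
    - "telehealth consult"
    - "delayed care"
  Age:
    - "67"
    - "34"
    - "82"
    - "19"
  Condition:
    - "pulmonary fibrosis"
    - "chronic fatigue"
    - "myocarditis"
    - "dysautonomia"
  Diet:
    - "vegan diet"
    - "low sodium diet"
    - "gluten free diet"
  Disability:
    - "hearing impairment"
    - "mobility limitation"
    - "visual impairment"
  Education:
    - "high school diploma"
    - "college degree"
    - "no formal schooling"
  Employment:
    - "night shift work"
    - "unemployed"
    - "factory worker"
  Exercise:
    - "daily walking"
    - "sedentary lifestyle"
    - "regular swimming"
  Family_Member:
    - "her daughter"
    - "his grandfather"
    - "their sibling"
  Gender:
    - "female"
    - "male"
    - "non binary"
  Geographic_Entity:
    - "rural Guatemala"
    - "northern Ontario"
    - "coastal Kenya"
  Housing:
    - "homeless shelter"
    - "transitional housing"
    - "overcrowded apartment"
  Income:
    - "low income"
    - "poverty line wages"
    - "fixed pension"
  Insurance_Status:
    - "uninsured"
    - "medicaid coverage"
    - "private insurance"
  Language:
    - "haitian creole"
    - "tagalog"
    - "amharic"
  Marital_Status:
    - "widowed"
    - "divorced"
    - "never married"
  Mental_Health:
    - "severe anxiety"
    - "postpartum depression"
    - "ptsd"
  Race_Ethnicity:
    - "afro caribbean"
    - "indigenous"
    - "south asian"
  Severity:
    - "critically severe"
    - "mild"
    - "life threatening"
  Sexual_Orientation:
    - "bisexual"
    - "gay"
    - "asexual"
  Social_Support:
    - "church volunteers"
    - "peer support group"
    - "no social support"
  Spiritual_Beliefs:
    - "buddhist practice"
    - "evangelical faith"
    - "animist beliefs"
  Substance:
    - "intravenous drug use"
    - "heavy drinking"
    - "vaping"
  Treatment:
    - "plasma exchange"
    - "pulmonary rehabilitation"
    - "corticosteroid taper"
  Vaccine:
    - "booster dose"
    - "unvaccinated status"
    - "two dose series"
  Violence_Or_Abuse:
    - "domestic violence"
    - "childhood abuse"
    - "workplace harassment"
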