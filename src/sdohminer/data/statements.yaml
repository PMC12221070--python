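# Per-entity-type NLI statements with entailment / contradiction term lists.
# Statements express presence/absence for binary attributes and a meaningful
# binary break for graded ones (education >= high school, white/Caucasian vs
# not, English vs not, senior adult, female-identifying, heterosexual,
# terminal/rare/chronic condition, highly invasive treatment, highly severe
# symptoms).  Term lists are illustrative fixtures; larger externally
# generated sets can replace them with the same layout.
statements:
  - id: access_to_care
    entity_type: Access_To_Care
    text: "Has access to care"
    entail: [clinic visit, hospital admission, follow up, telehealth, primary care, specialist referral, treated promptly]
    contradict: [delayed care, no access, denied care, unable to afford care, long wait, turned away]
  - id: senior_adult
    entity_type: Age
    text: "Is a senior adult"
    entail: [elderly, senior, octogenarian, "78", "82", "91", aged]
    contradict: [young, teenager, child, infant, "19", "34", "27", middle aged]
  - id: terminal_condition
    entity_type: Condition
    text: "Has a terminal, rare, or chronic condition"
    entail: [terminal, chronic, rare disease, chronic fatigue, pulmonary fibrosis, dysautonomia, incurable]
    contradict: [transient, self limiting, resolved, acute, mild infection]
  - id: dietary_restriction
    entity_type: Diet
    text: "Has dietary restrictions"
    entail: [vegan diet, gluten free diet, low sodium diet, restricted diet, fasting]
    contradict: [unrestricted diet, regular diet, no dietary restrictions]
  - id: has_disability
    entity_type: Disability
    text: "Has a disability"
    entail: [hearing impairment, mobility limitation, visual impairment, disabled, wheelchair]
    contradict: [no disability, fully able, able bodied]
  - id: high_school_education
    entity_type: Education
    text: "Has high school education or above"
    entail: [high school diploma, college degree, university, graduate degree, ged]
    contradict: [no formal schooling, illiterate, primary school only, dropped out]
  - id: is_employed
    entity_type: Employment
    text: "Is employed"
    entail: [factory worker, night shift work, employed, full time job, nurse, teacher]
    contradict: [unemployed, jobless, laid off, retired, out of work]
  - id: exercises_regularly
    entity_type: Exercise
    text: "Exercises regularly"
    entail: [daily walking, regular swimming, exercises regularly, active lifestyle, jogging]
    contradict: [sedentary lifestyle, no exercise, inactive, bedridden]
  - id: has_children
    entity_type: Family_Member
    text: "Has children"
    entail: [her daughter, his son, their children, his daughter, her son]
    contradict: [childless, no children, his grandfather, her mother, their sibling]
  - id: female_identifying
    entity_type: Gender
    text: "Is female-identifying"
    entail: [female, woman, girl, she]
    contradict: [male, man, boy, he]
  - id: english_speaking_country
    entity_type: Geographic_Entity
    text: "Is in an English-speaking country"
    entail: [united states, northern ontario, australia, united kingdom, canada]
    contradict: [rural guatemala, coastal kenya, japan, brazil, vietnam]
  - id: is_homeless
    entity_type: Housing
    text: "Is homeless"
    entail: [homeless shelter, homeless, unhoused, living on the street]
    contradict: [stable housing, owns a home, rents an apartment, transitional housing]
  - id: upper_middle_income
    entity_type: Income
    text: "Has upper-middle income or higher"
    entail: [high income, affluent, wealthy, well paid]
    contradict: [low income, poverty line wages, fixed pension, poor, impoverished]
  - id: has_insurance
    entity_type: Insurance_Status
    text: "Has medical insurance"
    entail: [medicaid coverage, private insurance, insured, medicare, covered]
    contradict: [uninsured, no insurance, lost coverage, lapsed policy]
  - id: english_primary_language
    entity_type: Language
    text: "Primary language is English"
    entail: [english]
    contradict: [haitian creole, tagalog, amharic, spanish, mandarin, interpreter needed]
  - id: is_married
    entity_type: Marital_Status
    text: "Is married"
    entail: [married, newlywed]
    contradict: [widowed, divorced, never married, single, separated]
  - id: mental_health_condition
    entity_type: Mental_Health
    text: "Has a mental health condition"
    entail: [severe anxiety, postpartum depression, ptsd, depression, psychosis]
    contradict: [no psychiatric history, mentally well, euthymic]
  - id: white_caucasian
    entity_type: Race_Ethnicity
    text: "Is white/Caucasian"
    entail: [white, caucasian]
    contradict: [afro caribbean, indigenous, south asian, black, hispanic, latino]
  - id: highly_severe
    entity_type: Severity
    text: "Symptoms are highly severe"
    entail: [critically severe, life threatening, severe, critical]
    contradict: [mild, moderate, minimal]
  - id: heterosexual
    entity_type: Sexual_Orientation
    text: "Is heterosexual"
    entail: [heterosexual, straight]
    contradict: [bisexual, gay, lesbian, asexual, queer]
  - id: has_social_support
    entity_type: Social_Support
    text: "Has social support"
    entail: [church volunteers, peer support group, supportive family, community support]
    contradict: [no social support, isolated, estranged, alone]
  - id: christian_faith
    entity_type: Spiritual_Beliefs
    text: "Follows a Christian faith"
    entail: [evangelical faith, catholic, christian, baptist]
    contradict: [buddhist practice, animist beliefs, muslim, hindu, atheist]
  - id: psychoactive_substances
    entity_type: Substance
    text: "Utilizes psychoactive substances"
    entail: [intravenous drug use, heavy drinking, vaping, cocaine, opioid use]
    contradict: [never smoked, abstinent, sober, no substance use]
  - id: invasive_treatment
    entity_type: Treatment
    text: "Has a highly invasive treatment"
    entail: [plasma exchange, surgery, intubation, transplant, dialysis]
    contradict: [pulmonary rehabilitation, corticosteroid taper, oral medication, physiotherapy, watchful waiting]
  - id: vaccinated
    entity_type: Vaccine
    text: "Is vaccinated against COVID-19"
    entail: [booster dose, two dose series, fully vaccinated, immunized]
    contradict: [unvaccinated status, unvaccinated, refused vaccine]
  - id: experienced_violence
    entity_type: Violence_Or_Abuse
    text: "Experienced violence or abuse"
    entail: [domestic violence, childhood abuse, workplace harassment, assaulted, battered]
    contradict: [no history of abuse, safe environment]
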