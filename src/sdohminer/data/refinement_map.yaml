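# Source-tagger entity type -> refined core type (or O to exclude).
# Grouping rationale: highly interrelated disease labels collapse into
# Condition; substance-related behaviours into Substance; admission /
# discharge events are treated as access to care; food insecurity as a
# dietary determinant; social exclusion as (lack of) social support;
# financial status as income.  Out-of-scope source types map to O.
mapping:
  # identity for the retained social / behavioural / clinical types
  Access_To_Care: Access_To_Care
  Age: Age
  Diet: Diet
  Disability: Disability
  Education: Education
  Employment: Employment
  Exercise: Exercise
  Family_Member: Family_Member
  Gender: Gender
  Geographic_Entity: Geographic_Entity
  Housing: Housing
  Income: Income
  Insurance_Status: Insurance_Status
  Language: Language
  Marital_Status: Marital_Status
  Mental_Health: Mental_Health
  Race_Ethnicity: Race_Ethnicity
  Severity: Severity
  Sexual_Orientation: Sexual_Orientation
  Social_Support: Social_Support
  Spiritual_Beliefs: Spiritual_Beliefs
  Substance: Substance
  Treatment: Treatment
  Vaccine: Vaccine
  Violence_Or_Abuse: Violence_Or_Abuse
  Condition: Condition
  # disease labels grouped into Condition
  Communicable_Disease: Condition
  Other_Disease: Condition
  Hypertension: Condition
  Hyperlipidemia: Condition
  Obesity: Condition
  Eating_Disorder: Condition
  # substance-related behaviours grouped into Substance
  Alcohol: Substance
  Smoking: Substance
  Substance_Use: Substance
  # other regroupings
  Admission_Discharge: Access_To_Care
  Food_Insecurity: Diet
  Social_Exclusion: Social_Support
  Financial_Status: Income
  # excluded source types -> non-entity class
  Community_Safety: O
  Date: O
  Healthcare_Institution: O
  Legal_Issues: O
  Other_SDoH_Keywords: O
  Population_Group: O
  Quality_Of_Life: O
  Sexual_Activity: O
  Substance_Duration: O
  Substance_Frequency: O
  Substance_Quantity: O
  Transportation: O
  Childhood_Event: O
  Environmental_Condition: O
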