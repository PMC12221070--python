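# Training-regime sentence templates for synthetic augmentation.
# {Type} marks an entity slot; every other whitespace token is a literal 'O'.
# The three templates jointly cover all 26 core entity types and keep the
# 'O' share low by design, so rare entities dominate the generated text.
templates:
  - id: train-1
    text: "{Age} {Race_Ethnicity} {Gender} with {Condition} and {Mental_Health} reported {Substance} while {Housing} on {Income} and {Employment}"
  - id: train-2
    text: "{Marital_Status} {Sexual_Orientation} speaker of {Language} from {Geographic_Entity} with {Education} and {Insurance_Status} had {Access_To_Care} receiving {Treatment} of {Severity}"
  - id: train-3
    text: "{Family_Member} provided {Social_Support} despite {Spiritual_Beliefs} with {Disability} following {Diet} doing {Exercise} after {Vaccine} and {Violence_Or_Abuse}"
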