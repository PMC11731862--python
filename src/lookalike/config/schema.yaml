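# Shared comparison-vector schema used by both source datasets after recoding.
variables:
  - name: sv_type
    family: binary
    categories: [other_sv, rape]
    reference: other_sv
  - name: perpetrator
    family: categorical
    categories: [domestic, acquaintance, stranger_unknown]
    reference: domestic
  - name: health_impact
    family: binary
    categories: [no_injury, injury]
    reference: no_injury
  - name: gender
    family: binary
    categories: [female, male]
    reference: female
  - name: relationship_status
    family: categorical
    categories: [married_cohabiting, single_widowed, separated_divorced]
    reference: married_cohabiting
  - name: ethnicity
    family: binary
    categories: [white, non_white]
    reference: white
  - name: employment
    family: categorical
    categories: [employed, unemployed, outside_labour_force, student]
    reference: employed
  - name: tenure
    family: categorical
    categories: [homeowner, renter, other]
    reference: homeowner
  - name: dependants
    family: count
  - name: age
    family: continuous
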