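# Default recode rules.  Only mappings with stated semantics are pre-filled;
# source systems with richer code inventories should extend these in a copy.
# Every harmonized label maps to itself so recoding is idempotent.
filters:
  age_column: age
  min_age: 16
rules:
  - target: sv_type
    source: violence_code
    delimiter: ";"
    mapping:
      rape: rape
      attempted rape: rape
      serious wounding with sexual motive: other_sv
      other wounding with sexual motive: other_sv
      indecent assault: other_sv
      sexual assault: other_sv
      assault by penetration: other_sv
      voyeurism: other_sv
      sexual bullying: other_sv
      penetration by object: other_sv
      gang related sexual violence: other_sv
      forced sexual activity in public: other_sv
      exposed to sexual images: other_sv
      sexual harassment: other_sv
      sexual exploitation: other_sv
      other_sv: other_sv
    priority: [rape, other_sv]
    drop:
      - childhood rape
      - childhood sexual abuse
      - other violence or abuse
  - target: perpetrator
    source: perpetrator
    delimiter: ";"
    mapping:
      partner: domestic
      former partner: domestic
      spouse: domestic
      family member: domestic
      domestic: domestic
      friend: acquaintance
      colleague: acquaintance
      neighbour: acquaintance
      acquaintance: acquaintance
      stranger: stranger_unknown
      unknown: stranger_unknown
      stranger_unknown: stranger_unknown
    priority: [domestic, acquaintance, stranger_unknown]
  - target: health_impact
    source: health_impact
    delimiter: ";"
    mapping:
      none: no_injury
      "no": no_injury
      no_injury: no_injury
      bruised: injury
      scratched: injury
      cut: injury
      injured: injury
      physical injuries: injury
      memory loss: injury
      body problems: injury
      gynaecological disorder: injury
      sexually transmitted infection: injury
      "yes": injury
      injury: injury
    priority: [injury, no_injury]
  - target: gender
    source: gender
    mapping:
      male: male
      man: male
      transgender male: male
      female: female
      woman: female
      transgender female: female
  - target: relationship_status
    source: relationship_status
    mapping:
      married: married_cohabiting
      cohabiting: married_cohabiting
      civil partnership: married_cohabiting
      married_cohabiting: married_cohabiting
      single: single_widowed
      non-resident partner: single_widowed
      widowed: single_widowed
      single_widowed: single_widowed
      separated: separated_divorced
      divorced: separated_divorced
      separated_divorced: separated_divorced
  - target: ethnicity
    source: ethnicity
    mapping:
      white: white
      white british: white
      white other: white
      black: non_white
      asian: non_white
      mixed: non_white
      other ethnicity: non_white
      non_white: non_white
  - target: employment
    source: employment
    mapping:
      employed: employed
      self-employed: employed
      unemployed: unemployed
      student: student
      homemaker: outside_labour_force
      retired: outside_labour_force
      unable to work: outside_labour_force
      outside_labour_force: outside_labour_force
  - target: tenure
    source: tenure
    mapping:
      homeowner: homeowner
      owns home: homeowner
      mortgage: homeowner
      renter: renter
      rents: renter
      social housing: renter
      living with family: other
      temporary accommodation: other
      homeless: other
      other: other
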