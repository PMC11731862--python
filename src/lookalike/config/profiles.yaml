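# Marginal distributions of the two shipped population profiles.
# Categorical entries are percentages as published; the loader renormalizes
# to probabilities.  Continuous variables give mean/sd of the *realized*
# (truncated) distribution; count variables give mean/sd matched by moments
# to a negative binomial.
profiles:
  csew:
    n_default: 1232
    categorical:
      sv_type: {rape: 32.4, other_sv: 67.6}
      perpetrator: {domestic: 24.6, acquaintance: 33.2, stranger_unknown: 42.2}
      health_impact: {no_injury: 60.9, injury: 39.1}
      gender: {male: 9.6, female: 90.4}
      relationship_status:
        married_cohabiting: 21.7
        single_widowed: 57.0
        separated_divorced: 21.4
      ethnicity: {white: 91.6, non_white: 8.4}
      employment:
        employed: 56.4
        unemployed: 7.6
        outside_labour_force: 30.4
        student: 5.6
      tenure: {homeowner: 34.6, renter: 59.8, other: 5.6}
    continuous:
      age: {mean: 32.9, sd: 12.4, lower: 16, integer: true}
    count:
      dependants: {mean: 0.6, sd: 1.0}
    cluster_rate: 0.0
  rcew:
    n_default: 6102
    categorical:
      sv_type: {rape: 70.7, other_sv: 29.3}
      perpetrator: {domestic: 48.2, acquaintance: 40.2, stranger_unknown: 11.6}
      health_impact: {no_injury: 94.0, injury: 6.0}
      gender: {male: 7.9, female: 92.1}
      relationship_status:
        married_cohabiting: 16.8
        single_widowed: 71.7
        separated_divorced: 11.6
      ethnicity: {white: 91.0, non_white: 9.0}
      employment:
        employed: 35.2
        unemployed: 38.2
        outside_labour_force: 11.7
        student: 14.9
      tenure: {homeowner: 41.8, renter: 18.4, other: 39.7}
    continuous:
      age: {mean: 34.1, sd: 12.9, lower: 16, integer: true}
    count:
      dependants: {mean: 0.8, sd: 1.2}
    cluster_rate: 0.0
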