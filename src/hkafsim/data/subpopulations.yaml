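# Physiological sampling distributions for the seven demographic
# subpopulations of the virtual population.
#
# Distribution kinds:
#   lognormal-arithmetic: central/spread are the arithmetic mean and SD of
#       the lognormal (converted internally by moment matching)
#   lognormal-geometric:  central/spread are the geometric mean and GSD
#   truncated-normal:     central/spread are the normal mean and SD
# lower/upper are hard truncation bounds enforced by rejection sampling.
#
# Body weight (kg) and hepatic CYP2E1 content (pmol/mg microsomal protein)
# are lognormal; the three dimensionless "variability terms" multiplying the
# allometric equations for alveolar ventilation (qp), liver volume (vl) and
# liver blood flow (ql) are truncated normals shared by every subgroup.
# cyp2e1 "same_as: adults" marks subgroups whose hepatic enzyme content is
# taken to be distributed as in adults.

_variability: &variability
  qp_var: {kind: truncated-normal, central: 1.0, spread: 0.10, lower: 0.80, upper: 1.20}
  vl_var: {kind: truncated-normal, central: 1.0, spread: 0.14, lower: 0.66, upper: 1.34}
  ql_var: {kind: truncated-normal, central: 1.0, spread: 0.13, lower: 0.67, upper: 1.33}

adults:
  age_range: "18-64 yr"
  body_weight: {kind: lognormal-arithmetic, central: 76, spread: 17, lower: 37, upper: 152}
  cyp2e1: {kind: lognormal-geometric, central: 49, spread: 2, lower: 11, upper: 130}
  <<: *variability

neonates:
  age_range: "0-30 d"
  body_weight: {kind: lognormal-arithmetic, central: 4, spread: 1, lower: 2, upper: 7}
  cyp2e1: {kind: lognormal-arithmetic, central: 18, spread: 14, lower: 1, upper: 56}
  <<: *variability

infants:
  age_range: "1-12 mo"
  body_weight: {kind: lognormal-arithmetic, central: 9, spread: 2, lower: 3, upper: 15}
  cyp2e1: {kind: lognormal-arithmetic, central: 36, spread: 21, lower: 10, upper: 86}
  <<: *variability

toddlers:
  age_range: "1-3 yr"
  body_weight: {kind: lognormal-arithmetic, central: 13, spread: 2, lower: 7, upper: 32}
  cyp2e1: {kind: lognormal-arithmetic, central: 42, spread: 18, lower: 18, upper: 74}
  <<: *variability

children_adolescents:
  age_range: "4-17 yr"
  body_weight: {kind: lognormal-arithmetic, central: 36, spread: 16, lower: 9, upper: 113}
  cyp2e1: {kind: lognormal-arithmetic, central: 53, spread: 23, lower: 22, upper: 95}
  <<: *variability

elderly:
  age_range: "65-90 yr"
  body_weight: {kind: lognormal-arithmetic, central: 72, spread: 16, lower: 33, upper: 155}
  cyp2e1: {same_as: adults}
  <<: *variability

pregnant_women:
  age_range: "15-44 yr"
  # body_weight is the non-pregnant women distribution; gestational weight
  # gain is drawn separately and added when computing the pregnant weight.
  body_weight: {kind: lognormal-arithmetic, central: 70, spread: 18, lower: 36, upper: 152}
  cyp2e1: {same_as: adults}
  pregnancy_gain: {kind: truncated-normal, central: 5, spread: 4.4, lower: 0, upper: 14.1}
  # Alveolar ventilation rises ~20-40% over gestation (progesterone-driven
  # increase in tidal volume) on top of the weight-gain effect; 1.25 is the
  # gestation-averaged increase applied to the allometric value at pregnant
  # body weight.
  qp_scale: 1.25
  <<: *variability
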