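# Reconstruction of a hypothetical population of 100,000 people with the
# demographic profile of Canada (2009 census proportions; pregnant women
# from a pregnancy rate of 104/1,000 among women aged 15-44).
name: canadian
counts:
  adults: 63923
  neonates: 93
  infants: 1015
  toddlers: 3322
  children_adolescents: 15866
  elderly: 13662
  pregnant_women: 2119
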