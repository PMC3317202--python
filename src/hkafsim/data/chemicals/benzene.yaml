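# Benzene: extensively cleared VOC (low blood:air partition coefficient,
# high hepatic extraction). Exposure set to 10x the RfC.
name: benzene
vmax_c: 2.11        # mg/h per kg^0.75 body weight
km: 0.1             # mg/L
pb: 7.4             # blood:air partition coefficient, dimensionless
exposure_conc: 0.3  # mg/m^3
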