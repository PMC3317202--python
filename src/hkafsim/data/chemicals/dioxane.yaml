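# 1,4-dioxane: poorly cleared VOC (very high blood:air partition
# coefficient, low hepatic extraction). Exposure ten times the benzene
# concentration, reflecting its roughly tenfold greater reference dose.
name: 1,4-dioxane
vmax_c: 0.27        # mg/h per kg^0.75 body weight
km: 3.0             # mg/L
pb: 3650            # blood:air partition coefficient, dimensionless
exposure_conc: 3    # mg/m^3
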