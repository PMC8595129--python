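# Translation constants and default drug configuration.
#
# Km factors are the standard body-surface-area dose-conversion constants
# (FDA guidance on estimating a maximum safe starting dose); reference
# weights in kg.  Drug defaults describe a nanoliposomal 20-mer antisense
# oligodeoxynucleotide: a polyanion, fully ionized at physiological pH,
# highly plasma-protein bound (fraction unbound from ultrafiltration).
bsa_km:
  mouse: 3
  rat: 6
  rabbit: 12
  monkey: 12
  dog: 20
  human: 37
reference_body_weight_kg:
  rat: 0.25
  monkey: 6.0
  human: 60.0
allometric_exponent_cl: 0.8
safety_factor_default: 10

drug:
  name: MK-ASODN nanoliposomes
  molecular_weight: 6044.4
  ionization_class: polyanion
  pka_list: []
  logp: -2.0
  blood_plasma_ratio: 1.0
  fup:                 # fraction unbound in plasma, by species
    human: 0.02
    monkey: 0.04
    rat: 0.035
plasma_ph: 7.4
lloq_ug_per_ml: 0.18
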