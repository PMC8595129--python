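# Reference whole-body physiology: rat
# Compiled from standard compendia of organ weights and regional blood flows
# (Brown et al. 1997, Toxicol Ind Health 13:407; Davies & Morris 1993,
# Pharm Res 10:1093), lumped to a 14-tissue perfusion-limited topology.
# rest_of_body closes mass and flow balance; unit tissue density assumed.
# Systemic compartments are perfused in parallel between the arterial and
# venous pools; lung carries total cardiac output.
# species: rat
# body_weight_kg: 0.25
# cardiac_output_L_per_h: 4.8
# hematocrit: 0.46
tissue,volume_L,flow_L_per_h
heart,0.000825,0.2352
lung,0.00125,4.8
brain,0.001425,0.096
adipose,0.0175,0.336
muscle,0.101,1.3344
skin,0.0475,0.2784
spleen,0.0005,0.048
reproductive,0.0025,0.024
gut,0.00675,0.6288
liver,0.00915,0.1152
kidney,0.001825,0.6768
yellow_marrow,0.0025,0.048
red_marrow,0.003,0.096
rest_of_body,0.023275,0.8832
arterial_blood,0.006167,4.8
venous_blood,0.012333,4.8
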