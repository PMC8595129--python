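# Reference whole-body physiology: human_chinese_male
# Compiled from standard compendia of organ weights and regional blood flows
# (Brown et al. 1997, Toxicol Ind Health 13:407; Davies & Morris 1993,
# Pharm Res 10:1093), lumped to a 14-tissue perfusion-limited topology.
# rest_of_body closes mass and flow balance; unit tissue density assumed.
# Systemic compartments are perfused in parallel between the arterial and
# venous pools; lung carries total cardiac output.
# species: human_chinese_male
# body_weight_kg: 60.0
# cardiac_output_L_per_h: 300.0
# hematocrit: 0.45
tissue,volume_L,flow_L_per_h
heart,0.282,12.0
lung,0.456,300.0
brain,1.38,36.0
adipose,9.0,15.0
muscle,24.0,51.0
skin,2.226,15.0
spleen,0.156,9.0
reproductive,0.048,0.15
gut,1.02,48.0
liver,1.56,19.5
kidney,0.264,57.0
yellow_marrow,1.44,4.5
red_marrow,1.14,9.0
rest_of_body,10.008,23.85
arterial_blood,1.54,300.0
venous_blood,3.08,300.0
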