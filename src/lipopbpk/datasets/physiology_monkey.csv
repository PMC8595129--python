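# Reference whole-body physiology: monkey
# Compiled from standard compendia of organ weights and regional blood flows
# (Brown et al. 1997, Toxicol Ind Health 13:407; Davies & Morris 1993,
# Pharm Res 10:1093), lumped to a 14-tissue perfusion-limited topology.
# rest_of_body closes mass and flow balance; unit tissue density assumed.
# Systemic compartments are perfused in parallel between the arterial and
# venous pools; lung carries total cardiac output.
# species: monkey
# body_weight_kg: 6.0
# cardiac_output_L_per_h: 60.0
# hematocrit: 0.4
tissue,volume_L,flow_L_per_h
heart,0.021,3.0
lung,0.042,60.0
brain,0.09,4.8
adipose,0.42,1.8
muscle,2.58,9.0
skin,0.57,3.6
spleen,0.009,0.9
reproductive,0.012,0.18
gut,0.168,8.4
liver,0.162,3.0
kidney,0.0264,8.4
yellow_marrow,0.09,0.6
red_marrow,0.09,1.8
rest_of_body,1.0296,14.52
arterial_blood,0.13,60.0
venous_blood,0.26,60.0
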