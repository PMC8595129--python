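# Observed plasma PK parameters (mean, sd) by dose group from the monkey
# single-IV-dose study of MK-ASODN nanoliposomes (3 macaques per group).
# dose in mg/kg; AUCinf in ug.h/ml; Cmax in ug/ml; MRT and t_half in h;
# CL in ml/kg/h; Vss in ml/kg.
parameter,dose_mg_per_kg,n,mean,sd
AUCinf,11.5,3,122.04,17.27
AUCinf,23,3,232.87,18.14
AUCinf,46,3,415.38,22.21
Cmax,11.5,3,187.16,102.84
Cmax,23,3,347.43,156.01
Cmax,46,3,588.73,88.88
MRT,11.5,3,0.90,0.45
MRT,23,3,1.04,0.26
MRT,46,3,1.23,0.16
CL,11.5,3,95.41,12.53
CL,23,3,99.16,7.64
CL,46,3,110.95,5.91
Vss,11.5,3,88.41,51.87
Vss,23,3,104.63,34.41
Vss,46,3,137.89,25.53
t_half,11.5,3,0.79,0.21
t_half,23,3,1.08,0.18
t_half,46,3,1.33,0.05
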