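# Tissue composition for partition-coefficient prediction.
# f_ew / f_iw: fractional extracellular / intracellular water (v/v);
# f_nl / f_np: fractional neutral lipid / neutral phospholipid (v/v);
# ap_mg_per_g: acidic phospholipid concentration; albumin_ratio:
# tissue:plasma albumin ratio; ph_iw: intracellular pH.
# Values compiled from the tissue-composition tables of Rodgers & Rowland
# (2006, J Pharm Sci 95:1238) and Rodgers, Leahy & Rowland (2005, J Pharm
# Sci 94:1259); reproductive, marrow and rest_of_body entries are lumped
# analogues (yellow marrow ~ adipose, red marrow ~ bone, rest ~ mixed lean).
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_per_g,albumin_ratio,ph_iw
adipose,0.135,0.017,0.846,0.0016,0.40,0.049,7.0
brain,0.162,0.620,0.039,0.0015,0.40,0.048,7.0
gut,0.282,0.475,0.038,0.0125,2.41,0.158,7.0
heart,0.320,0.456,0.014,0.0111,2.25,0.157,7.0
kidney,0.273,0.483,0.012,0.0240,5.03,0.130,7.0
liver,0.161,0.573,0.014,0.0240,4.56,0.086,7.0
lung,0.336,0.446,0.022,0.0128,3.91,0.212,7.0
muscle,0.118,0.630,0.010,0.0072,1.53,0.064,7.0
skin,0.382,0.291,0.060,0.0044,1.32,0.277,7.0
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097,7.0
reproductive,0.255,0.510,0.0170,0.0092,2.30,0.110,7.0
yellow_marrow,0.135,0.017,0.846,0.0016,0.40,0.049,7.0
red_marrow,0.100,0.346,0.0170,0.0017,0.67,0.100,7.0
rest_of_body,0.200,0.520,0.0220,0.0080,1.80,0.100,7.0
jejunum,0.282,0.475,0.038,0.0125,2.41,0.158,7.0
stomach,0.282,0.475,0.038,0.0125,2.41,0.158,7.0
fat,0.135,0.017,0.846,0.0016,0.40,0.049,7.0
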