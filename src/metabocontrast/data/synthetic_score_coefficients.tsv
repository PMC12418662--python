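analyte	weight
XXL_VLDL_L	0.32
S_HDL_L	0.24
VLDL_D	0.18
PUFA_by_FA	0.21
Histidine	0.27
Leucine	0.35
Valine	0.22
Albumin	0.15
Glucose	-0.29
Lactate	-0.17
Isoleucine	-0.33
Phenylalanine	-0.26
Acetoacetate	-0.19
GlycA	-0.31
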