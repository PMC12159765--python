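label	hemisphere	region
HES_L	L	Heschl gyrus
HES_R	R	Heschl gyrus
STG_L	L	superior temporal gyrus
STG_R	R	superior temporal gyrus
MTG_L	L	middle temporal gyrus
MTG_R	R	middle temporal gyrus
ITG_L	L	inferior temporal gyrus
ITG_R	R	inferior temporal gyrus
ORBsup_L	L	superior orbitofrontal cortex
ORBsup_R	R	superior orbitofrontal cortex
ORBmid_L	L	middle orbitofrontal cortex
ORBmid_R	R	middle orbitofrontal cortex
ORBinf_L	L	inferior orbitofrontal cortex
ORBinf_R	R	inferior orbitofrontal cortex
ACG_L	L	anterior cingulate gyrus
ACG_R	R	anterior cingulate gyrus
DCG_L	L	dorsal cingulate gyrus
DCG_R	R	dorsal cingulate gyrus
PCG_L	L	posterior cingulate gyrus
PCG_R	R	posterior cingulate gyrus
HIP_L	L	hippocampus
HIP_R	R	hippocampus
PHG_L	L	parahippocampal gyrus
PHG_R	R	parahippocampal gyrus
INS_L	L	insula
INS_R	R	insula
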