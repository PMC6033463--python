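res_a	res_b	opened	compact
1	95	yes	yes
1	233	no	yes
1	242	no	yes
69	75	yes	yes
69	95	yes	yes
72	95	yes	yes
72	233	no	yes
72	242	no	yes
72	282	yes	no
75	95	yes	yes
75	143	no	yes
75	242	no	yes
95	143	no	yes
95	157	no	yes
95	233	no	yes
95	242	no	yes
95	262	yes	no
95	282	yes	no
143	233	yes	yes
157	233	yes	yes
157	242	yes	yes
233	242	yes	yes
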