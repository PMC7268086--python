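name	x_mni	y_mni	z_mni	partition
LAG	-43	-76	35	posterior
RAG	51	-64	32	posterior
LPCC	-3	-54	31	posterior
RPCC	3	-54	31	posterior
LvMPFC	-2	51	2	anterior
LdMPFC	-13	52	23	anterior
RdMPFC	2	53	24	anterior
RvMPFC	2	51	2	anterior
LITG	-57	-25	-17	posterior
RITG	57	-25	-17	posterior
LACC	-6	-36	31	anterior
RACC	6	-36	31	anterior
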