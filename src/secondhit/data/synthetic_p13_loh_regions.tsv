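sample	region_id	uncertain
S14	R1	no
S15	R1	no
S17	R1	no
S18	R1	no
S19	R1	no
S20	R2	no
S21	R3	no
S22		yes
S23	R2	no
S24	R2	no
S25	R4	no
S29	R5	no
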