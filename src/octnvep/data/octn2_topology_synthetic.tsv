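name	class	start	end
N-term	N-term	1	45
TM1	TM	46	66
EL1	EL	67	156
TM2	TM	157	177
IL1	IL	178	192
TM3	TM	193	213
EL2	EL	214	217
TM4	TM	218	238
IL2	IL	239	253
TM5	TM	254	274
EL3	EL	275	286
TM6	TM	287	307
IL3	IL	308	322
TM7	TM	323	343
EL4	EL	344	353
TM8	TM	354	374
IL4	IL	375	389
TM9	TM	390	410
EL5	EL	411	413
TM10	TM	414	434
IL5	IL	435	449
TM11	TM	450	470
EL6	EL	471	482
TM12	TM	483	503
C-term	C-term	504	557
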