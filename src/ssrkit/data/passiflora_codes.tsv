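locus	code	size_bp
ssr1	A	87
ssr1	B	93
ssr1	C	99
ssr1	D	105
ssr1	E	117
ssr2	A	175
ssr2	B	193
ssr2	C	199
ssr2	D	203
ssr2	E	205
ssr2	F	211
ssr2	G	307
ssr3	A	220
ssr3	B	226
ssr3	C	232
ssr3	D	238
ssr3	E	244
ssr3	F	250
ssr18	A	305
ssr18	B	342
ssr18	C	347
ssr18	D	357
ssr18	E	362
ssr18	F	366
ssr18	G	367
ssr18	H	372
ssr18	I	377
ssr18	J	387
ssr30	A	248
ssr30	B	252
ssr30	C	256
ssr30	D	260
ssr32	A	144
ssr32	B	156
ssr32	C	160
ssr32	D	164
ssr32	E	168
ssr32	F	172
ssr32	G	176
ssr32	H	180
ssr32	I	184
ssr32	J	188
ssr32	K	192
ssr32	L	196
ssr32	M	204
ssr32	N	212
ssr32	O	224
ssr34	A	130
ssr34	B	198
ssr34	C	202
ssr34	D	206
ssr34	E	209
ssr34	F	210
ssr34	G	322
ssr39	A	239
ssr39	B	243
ssr39	C	251
ssr39	D	259
ssr39	E	267
ssr39	F	275
ssr39	G	279
ssr39	H	283
ssr39	I	287
ssr39	J	291
ssr39	K	295
ssr39	L	299
ssr39	M	307
ssr39	N	315
ssr39	O	319
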