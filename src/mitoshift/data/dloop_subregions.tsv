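name	start	end
MT-HV1	16024	16383
MT-TAS2	16081	16138
MT-TAS	16157	16172
MT-7SDNA	16106	191
MT-HV2	57	372
MT-OHR	110	441
MT-CSB1	213	235
MT-TFX	233	260
MT-TFY	276	303
MT-CSB2	299	315
MT-CSB3	346	363
MT-MT4H	371	379
MT-MT3L	384	391
MT-LSP	392	445
MT-TFL	418	445
MT-TFH	523	550
MT-HSP1	545	567
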