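chrM	301	316	polyC_D310
chrM	512	526	AC_repeat_514
chrM	3104	3110	polyC_3107
chrM	16180	16194	polyC_16184
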