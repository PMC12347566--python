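model_name	np	lnL
one_ratio	1	-8845.89
two_branch_C4	2	-8841.77
three_branch	3	-8843.84
four_branch	4	-8839.68
modelA_C4	4	-8802.28
modelA_null_C4	3	-8810.99
modelA_Chr5	4	-8818.62
modelA_null_Chr5	3	-8820.80
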