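	Hedou 12	Williams 82	Jilin 35	Jack	HVE	Essex	Forrest	Wandou 28	Jindou 21	Fendou 33	Shidou 111	Andou 1311	Zhonghuang 30	Zhoudou 17
Hedou 12		165	102	130	130	94	104	66	72	83	82	76	94	71
Williams 82	100%		67	31	36	69	63	102	91	75	70	78	70	92
Jilin 35	62%	41%		59	61	56	58	80	69	71	67	78	78	67
Jack	79%	19%	36%		40	58	56	87	71	67	68	75	66	76
HVE	79%	22%	37%	24%		52	64	96	85	81	61	79	76	83
Essex	57%	42%	34%	35%	32%		48	65	70	68	62	53	75	68
Forrest	63%	38%	35%	34%	39%	29%		72	80	70	73	58	70	64
Wandou 28	40%	62%	48%	53%	58%	39%	44%		64	65	71	61	93	46
Jindou 21	44%	55%	42%	43%	52%	42%	48%	39%		27	68	66	69	52
Fendou 33	50%	45%	43%	41%	49%	41%	42%	39%	16%		61	61	66	57
Shidou 111	50%	42%	41%	41%	37%	38%	44%	43%	41%	37%		84	69	64
Andou 1311	46%	47%	47%	45%	48%	32%	35%	37%	40%	37%	51%		73	65
Zhonghuang 30	57%	42%	47%	40%	46%	45%	42%	56%	42%	40%	42%	44%		78
Zhoudou 17	43%	56%	41%	46%	50%	41%	39%	28%	32%	35%	39%	39%	47%
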