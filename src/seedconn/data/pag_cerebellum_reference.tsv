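structure	hemisphere	compartment	mean_delta_norm	sd	cov
Right fastigial nucleus	right	nuclear	17.24	8.41	0.49
Vermis IX	midline	posterior	12.43	6.02	0.48
Right interposed nucleus	right	nuclear	10.75	6.09	0.57
Left fastigial nucleus	left	nuclear	10.47	5.44	0.52
Vermis VIIIa	midline	posterior	9.90	5.38	0.54
Right Lobule IX	right	posterior	9.20	4.07	0.44
Left Lobule IX	left	posterior	5.81	2.97	0.51
Vermis VI	midline	posterior	5.07	3.52	0.69
Right dentate nucleus	right	nuclear	4.56	3.27	0.72
Vermis X	midline	flocculonodular	4.52	3.14	0.69
Left interposed nucleus	left	nuclear	4.29	3.58	0.84
Left dentate nucleus	left	nuclear	1.81	1.60	0.89
Vermis VIIIb	midline	posterior	1.72	1.18	0.69
Right Crus II	right	posterior	0.51	0.58	1.12
Right Lobule X	right	flocculonodular	0.43	0.70	1.62
Left Lobule X	left	flocculonodular	0.21	0.30	1.39
Left Crus II	left	posterior	0.18	0.20	1.10
Right Lobules I-IV	right	anterior	0.15	0.10	0.66
Right Lobule VIIIa	right	posterior	0.13	0.14	1.07
Left Lobule V	left	anterior	0.09	0.20	2.25
Right Lobule V	right	anterior	0.08	0.20	2.54
Right Lobule VIIb	right	posterior	0.07	0.09	1.31
Right Lobule VIIIb	right	posterior	0.07	0.13	1.89
Left Lobule VIIIb	left	posterior	0.07	0.08	1.20
Left Lobules I-IV	left	anterior	0.06	0.05	0.75
Left Lobule VIIIa	left	posterior	0.05	0.06	1.03
Right Crus I	right	posterior	0.04	0.06	1.63
Left Lobule VIIb	left	posterior	0.04	0.04	1.04
Vermis VIIb	midline	posterior	0.02	0.03	1.44
Right Lobule VI	right	posterior	0.01	0.03	2.55
Left Crus I	left	posterior	0.01	0.02	1.25
Vermis Crus II	midline	posterior	0.01	0.02	2.27
Left Lobule VI	left	posterior	0.01	0.01	1.96
Vermis Crus I	midline	posterior	0.00	0.00	0.00
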