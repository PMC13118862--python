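mag_id	completeness	contamination	genome_size
MAG_1	43.51	5.53	1.04
MAG_2	39.14	7.74	1.21
MAG_3	41.89	6.25	1.32
MAG_4	38.20	8.57	1.86
MAG_5	35.37	3.85	1.03
MAG_6	26.66	9.02	1.11
MAG_7	38.41	6.15	1.03
MAG_8	35.32	5.13	1.05
MAG_9	41.88	7.44	1.08
MAG_10	92.89	6.41	2.15
MAG_11	34.75	1.96	1.03
MAG_12	97.99	1.59	5.64
MAG_13	98.88	2.24	4.29
MAG_14	89.12	3.26	4.20
MAG_15	45.03	9.06	2.37
MAG_16	97.60	0.20	4.75
MAG_17	83.08	4.89	5.09
MAG_18	92.41	2.30	4.12
MAG_19	71.81	3.33	5.81
MAG_20	22.98	1.90	1.69
MAG_21	98.00	0.60	4.79
MAG_22	96.53	5.60	5.22
MAG_23	100.00	0.00	4.83
MAG_24	82.71	5.20	2.34
MAG_25	34.80	7.92	1.02
MAG_26	40.44	3.93	1.08
MAG_27	34.69	4.51	1.03
MAG_28	43.66	3.14	5.14
MAG_29	35.73	1.62	1.29
MAG_30	27.58	7.02	1.55
MAG_31	20.69	0.00	1.02
MAG_32	46.36	1.01	1.00
MAG_33	32.56	3.34	1.01
MAG_34	48.63	7.45	1.33
MAG_35	21.98	0.88	1.08
MAG_36	26.72	4.10	1.48
MAG_37	44.10	1.77	1.12
MAG_38	56.25	0.00	1.04
MAG_39	63.58	1.27	1.23
MAG_40	68.93	1.51	1.71
MAG_41	33.62	6.90	1.31
MAG_42	99.36	0.32	3.35
MAG_43	36.21	0.00	1.39
MAG_44	87.01	0.94	3.37
MAG_45	82.22	1.05	2.81
MAG_46	95.48	7.60	6.00
MAG_47	81.88	2.05	3.98
MAG_48	55.33	0.00	2.21
MAG_49	22.28	0.00	1.05
MAG_50	41.53	0.00	2.22
MAG_51	53.33	0.00	2.20
MAG_52	73.27	1.93	3.38
MAG_53	60.09	0.27	1.28
MAG_54	70.18	0.00	1.83
MAG_55	94.80	0.00	4.39
MAG_56	25.86	0.00	1.02
MAG_57	93.80	0.13	4.43
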