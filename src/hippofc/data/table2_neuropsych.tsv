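subject_id	group	dichotic_listening	estimated_iq	boston_naming_z	verbal_fluency_z	vigilance_errors	wmsr_general_memory_z	wmsr_verbal_memory_z	wmsr_visual_memory_z	wmsr_delayed_recall_z
right_mtle_01	right_mtle	left	100	0.12	-0.63	0	1.23	1.53	-0.05	1.95
right_mtle_02	right_mtle	NA	97	-4.8	-0.63	0	0.4	0.68	-0.37	-0.24
right_mtle_03	right_mtle	left	86	-3.39	-0.19	0	-0.55	-0.54	-0.76	-1.02
right_mtle_04	right_mtle	left	100	-2.13	-0.85	1	0.46	-0.02	1.68	-0.45
right_mtle_05	right_mtle	left	115	-0.11	0.02	0	2.38	2.96	0.46	3.16
right_mtle_06	right_mtle	left	100	1.32	0.46	1	0.9	0.77	0.63	0.48
right_mtle_07	right_mtle	left	97	-0.58	-0.85	0	1.29	1.07	1.04	1.88
right_mtle_08	right_mtle	left	92	-1.11	NA	0	-0.04	0.07	-0.11	-1
right_mtle_09	right_mtle	left	NA	NA	NA	NA	NA	NA	NA	NA
left_mtle_01	left_mtle	left	89	-1.27	0.46	0	-0.04	-0.22	0.27	-0.03
left_mtle_02	left_mtle	left	88	-4.49	-0.85	0	-1.25	-1.12	-0.5	-0.24
left_mtle_03	left_mtle	left	80	-5.01	-1.02	1	-0.23	-0.22	-0.24	-1.3
left_mtle_04	left_mtle	NA	94	-1.26	-0.85	0	-0.76	-1.19	0.78	-0.77
left_mtle_05	left_mtle	left	94	-2.69	-0.19	0	-0.83	-1.55	0.59	-0.65
left_mtle_06	left_mtle	left	89	-1	1.34	0	-0.04	-0.09	0.01	-0.59
left_mtle_07	left_mtle	left	80	-7.97	-1.64	0	-1.83	-2.3	0.01	-1.73
left_mtle_08	left_mtle	left	NA	NA	NA	NA	NA	NA	NA	NA
left_mtle_09	left_mtle	left	86	-4.45	NA	0	-1.51	-1.12	-1.53	-3.15
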