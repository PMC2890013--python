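subject_id	group	vlh_mm3	vrh_mm3
control_01	control	4126	4964
control_02	control	4607	4398
control_03	control	4852	4521
control_04	control	6170	5266
control_05	control	4979	4521
control_06	control	4312	4438
control_07	control	4545	4436
control_08	control	4728	4938
control_09	control	5740	5378
right_mtle_01	right_mtle	4437	3215
right_mtle_02	right_mtle	6400	4885
right_mtle_03	right_mtle	3340	2416
right_mtle_04	right_mtle	5122	3689
right_mtle_05	right_mtle	5014	3033
right_mtle_06	right_mtle	3841	3493
right_mtle_07	right_mtle	4371	3373
right_mtle_08	right_mtle	5143	3408
right_mtle_09	right_mtle	6113	2870
left_mtle_01	left_mtle	2589	4545
left_mtle_02	left_mtle	5919	6440
left_mtle_03	left_mtle	3902	4476
left_mtle_04	left_mtle	3384	4777
left_mtle_05	left_mtle	5551	5770
left_mtle_06	left_mtle	3842	4653
left_mtle_07	left_mtle	2194	3440
left_mtle_08	left_mtle	2943	5224
left_mtle_09	left_mtle	3481	4601
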