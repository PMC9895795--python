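code	genotype	stage	mean_ug_per_g	se_ug_per_g	n
v06	SF	ES	692.9	5.72	3
v02	SF	ES	65.82	4.81	3
v22	SF	ES	56.35	4.96	3
v07	SF	ES	394.7	7.84	3
v13	SF	ES	384.79	9.43	3
v08	SF	ES	233.12	45.38	3
v01	SF	ES	201.16	52.52	3
v28	SF	ES	193.48	22.9	3
v12	SF	ES	128.96	4.71	3
v67	SF	ES	128.88	28.29	3
v10	SF	ES	419.96	6.05	3
v04	SF	ES	80.87	4.93	3
v25	SF	ES	668.47	15.69	3
v16	SF	ES	48.48	6.02	3
v26	SF	ES	390.2	2.14	3
v27	SF	ES	379.57	3.7	3
v21	SF	ES	39.19	4.47	3
v29	SF	ES	31.53	0.81	3
v30	SF	ES	14.27	0.28	3
v18	SF	ES	10.45	0.4	3
v06	WF	ES	476.46	5.08	3
v02	WF	ES	53.25	1.44	3
v22	WF	ES	11.99	0.9	3
v07	WF	ES	54.97	0.84	3
v13	WF	ES	61.93	2.5	3
v08	WF	ES	83.93	4.58	3
v01	WF	ES	40.72	0.26	3
v28	WF	ES	218.99	6.67	3
v12	WF	ES	6.19	0.11	3
v67	WF	ES	60.3	0.42	3
v04	WF	ES	17.78	2.74	3
v25	WF	ES	243.03	8.28	3
v40	WF	ES	92.6	1.3	3
v05	WF	ES	68.92	1.36	3
v23	WF	ES	49.69	2.59	3
v41	WF	ES	44.47	4.28	3
v42	WF	ES	43.76	4.28	3
v09	WF	ES	39.19	1.0	3
v06	Mr	ES	411.88	7.11	3
v02	Mr	ES	21.27	0.79	3
v22	Mr	ES	55.13	1.18	3
v07	Mr	ES	154.38	3.88	3
v13	Mr	ES	18.54	1.42	3
v08	Mr	ES	73.48	2.36	3
v01	Mr	ES	32.12	0.59	3
v28	Mr	ES	8.51	1.04	3
v12	Mr	ES	9.74	0.08	3
v10	Mr	ES	217.17	10.38	3
v16	Mr	ES	17.42	0.59	3
v47	Mr	ES	91.57	1.66	3
v20	Mr	ES	89.1	2.48	3
v31	Mr	ES	78.56	1.98	3
v44	Mr	ES	64.96	0.18	3
v48	Mr	ES	52.57	1.95	3
v49	Mr	ES	31.31	0.2	3
v50	Mr	ES	31.14	0.23	3
v35	Mr	ES	29.03	0.17	3
v51	Mr	ES	11.41	1.14	3
v52	Mr	ES	8.09	0.13	3
v53	Mr	ES	5.24	0.31	3
v54	Mr	ES	3.91	0.54	3
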