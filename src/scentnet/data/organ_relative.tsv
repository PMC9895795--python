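code	organ	percent	se
v25	petal	51.92	0.72
v26	petal	13.46	1.68
v57	petal	9.86	0.45
v07	petal	4.3	0.44
v10	petal	11.84	1.18
v50	petal	1.64	0.11
v06	petal	0.27	0.01
v23	petal	3.96	0.15
v66	petal	0.84	0.09
v12	petal	0.72	0.08
v27	petal	1.18	0.34
v25	stamen	47.0	0.84
v26	stamen	17.94	0.53
v57	stamen	5.5	0.37
v07	stamen	4.74	0.34
v10	stamen	4.69	0.22
v01	stamen	4.58	0.45
v50	stamen	2.1	0.18
v06	stamen	2.06	0.16
v28	stamen	2.44	0.11
v60	stamen	1.15	0.04
v61	stamen	0.75	0.04
v62	stamen	1.05	0.13
v63	stamen	0.53	0.03
v64	stamen	0.48	0.02
v38	stamen	1.63	0.81
v65	stamen	0.54	0.04
v11	stamen	0.94	0.03
v27	stamen	1.88	0.12
v25	pistil	50.91	2.52
v26	pistil	26.8	3.38
v06	pistil	6.01	0.77
v28	pistil	6.37	0.21
v60	pistil	3.36	0.42
v63	pistil	2.56	1.02
v20	pistil	3.98	0.19
v25	calyx_bracts	41.3	1.12
v26	calyx_bracts	23.57	1.14
v41	calyx_bracts	9.95	0.3
v57	calyx_bracts	6.12	0.41
v07	calyx_bracts	4.85	0.22
v10	calyx_bracts	2.79	0.16
v34	calyx_bracts	1.78	0.07
v01	calyx_bracts	1.44	0.07
v50	calyx_bracts	1.29	0.04
v06	calyx_bracts	1.27	0.02
v58	calyx_bracts	0.82	0.07
v28	calyx_bracts	0.81	0.03
v59	calyx_bracts	0.81	0.03
v60	calyx_bracts	0.81	0.03
v61	calyx_bracts	0.7	0.01
v62	calyx_bracts	0.61	0.07
v63	calyx_bracts	0.58	0.05
v64	calyx_bracts	0.49	0.06
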