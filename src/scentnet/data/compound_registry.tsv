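name	code	class	threshold_ng_per_g	threshold_low_ng_per_g	threshold_high_ng_per_g
Methyl benzoate	v06	benzenoid_phenylpropanoid	0.52		
Methyl laurate	v02	fatty_acid_derivative			
Methyl hexanoate	v22	fatty_acid_derivative			
(E)-3-Hexen-1-ol	v07	fatty_acid_derivative	1550		
1,3-Dimethylbenzene	v13	benzenoid_phenylpropanoid			
Decane	v08	other			
Linalool	v01	terpenoid			
Benzaldehyde	v28	benzenoid_phenylpropanoid			
Naphthalene	v12	benzenoid_phenylpropanoid			
Methyl octanoate	v67	fatty_acid_derivative			
Leaf acetate	v10	fatty_acid_derivative	12.1		
Methyl hexadecanoate	v04	fatty_acid_derivative			
Benzyl alcohol	v25	benzenoid_phenylpropanoid	10000		
Methyl 2-methylbutyrate	v16	fatty_acid_derivative			
Methyl anthranilate	v26	benzenoid_phenylpropanoid	3.0		
Hexyl alcohol	v27	fatty_acid_derivative	2500		
Methyl acetate	v21	fatty_acid_derivative			
Propylcyclopropane	v29	other			
2-Methyldecane	v30	other			
4-Methyl-Decanes	v18	other			
1-Phenylpropane-1,2-diol	v40	benzenoid_phenylpropanoid			
Linalyl acetate	v05	terpenoid			
2-Ethylhexanol	v23	fatty_acid_derivative			
Indole	v41	benzenoid_phenylpropanoid			
Tetracosane	v42	other			
Methyl tetradecanoate	v09	fatty_acid_derivative			
Methyl 2-Ethylhexanoate	v47	fatty_acid_derivative			
cis-3-Hexenyl formate	v20	fatty_acid_derivative			
4-Methoxy phenyl oxime	v31	benzenoid_phenylpropanoid			
Cyclohexanol	v44	other			
Methyl 2-methyl-2-butenoate	v48	fatty_acid_derivative			
Hexyl acetate	v49	fatty_acid_derivative			
Benzyl acetate	v50	benzenoid_phenylpropanoid			
Methyl heptenone	v35	terpenoid			
Acethydrazide	v51	other			
2-Methylgeng acid	v52	fatty_acid_derivative			
2-Methylcyclopentalol	v53	other			
Methyl butyrate	v54	fatty_acid_derivative			
Cinnamyl alcohol	v57	benzenoid_phenylpropanoid			
Linalyl butyrate	v34	terpenoid			
Geranylacetone	v58	terpenoid			
cis-3-Hexenyl benzoate	v59	benzenoid_phenylpropanoid			
Phenethyl alcohol	v60	benzenoid_phenylpropanoid			
3-Phenyl-1-propanol	v61	benzenoid_phenylpropanoid			
Cinnamaldehyde	v62	benzenoid_phenylpropanoid			
Benzyl 2-methyl-2-butenoate	v63	benzenoid_phenylpropanoid			
Pentanoic acid	v64	benzenoid_phenylpropanoid			
3-Aminophenylacetylene	v38	benzenoid_phenylpropanoid			
Benzyl benzoate	v65	benzenoid_phenylpropanoid			
Benzyl butyrate	v66	benzenoid_phenylpropanoid			
Heneicosane	v11	other			
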