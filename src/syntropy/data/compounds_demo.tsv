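compound_id	name	formula	monoisotopic_mass	source_db	kegg_pathways	origin_class
CPD0001	D-Glucose	C6H12O6	180.063388	demo	Starch and sucrose metabolism|Glycolysis / Gluconeogenesis	plant
CPD0002	Butyrate	C4H8O2	88.052429	demo	Butanoate metabolism|Fatty acid biosynthesis	bacterial
CPD0003	Propionate	C3H6O2	74.036779	demo	Propanoate metabolism	bacterial
CPD0004	Acetate	C2H4O2	60.021129	demo	Pyruvate metabolism|Fatty acid biosynthesis	bacterial
CPD0005	L-Lactate	C3H6O3	90.031694	demo	Pyruvate metabolism|Glycolysis / Gluconeogenesis	bacterial
CPD0006	Succinate	C4H6O4	118.026609	demo	Citrate cycle (TCA cycle)|Butanoate metabolism	bacterial
CPD0007	L-Tryptophan	C11H12N2O2	204.089878	demo	Tryptophan metabolism|Aminoacyl-tRNA biosynthesis	mammalian
CPD0008	L-Tyrosine	C9H11NO3	181.073893	demo	Tyrosine metabolism	mammalian
CPD0009	L-Phenylalanine	C9H11NO2	165.078979	demo	Phenylalanine metabolism	mammalian
CPD0010	Nicotinate	C6H5NO2	123.032028	demo	Nicotinate and nicotinamide metabolism	bacterial
CPD0011	Glutathione	C10H17N3O6S	307.083806	demo	Glutathione metabolism	mammalian
CPD0012	Taurine	C2H7NO3S	125.014664	demo	Taurine and hypotaurine metabolism	mammalian
CPD0013	Cholic acid	C24H40O5	408.287574	demo	Primary bile acid biosynthesis	mammalian
CPD0014	Deoxycholic acid	C24H40O4	392.292660	demo	Secondary bile acid biosynthesis	bacterial
CPD0015	Urobilinogen	C33H44N4O6	592.326085	demo	Porphyrin and chlorophyll metabolism	bacterial
CPD0016	L-Urobilin	C33H42N4O6	590.310435	demo	Porphyrin and chlorophyll metabolism	bacterial
CPD0017	Spermidine	C7H19N3	145.157898	demo	Arginine and proline metabolism	mammalian
CPD0018	Putrescine	C4H12N2	88.100048	demo	Arginine and proline metabolism	bacterial
CPD0019	Indole	C8H7N	117.057849	demo	Tryptophan metabolism	bacterial
CPD0020	Indole-3-acetate	C10H9NO2	175.063329	demo	Tryptophan metabolism	bacterial
CPD0021	4-Aminobutanoate	C4H9NO2	103.063329	demo	Alanine, aspartate and glutamate metabolism|Butanoate metabolism	bacterial
CPD0022	L-Glutamate	C5H9NO4	147.053158	demo	Alanine, aspartate and glutamate metabolism|Glutathione metabolism	mammalian
CPD0023	L-Arginine	C6H14N4O2	174.111676	demo	Arginine and proline metabolism	mammalian
CPD0024	Citrulline	C6H13N3O3	175.095691	demo	Arginine and proline metabolism	mammalian
CPD0025	Uracil	C4H4N2O2	112.027277	demo	Pyrimidine metabolism	mammalian
CPD0026	Hypoxanthine	C5H4N4O	136.038511	demo	Purine metabolism	mammalian
CPD0027	Inosine	C10H12N4O5	268.080770	demo	Purine metabolism	mammalian
CPD0028	Riboflavin	C17H20N4O6	376.138284	demo	Riboflavin metabolism	bacterial
CPD0029	Pantothenate	C9H17NO5	219.110673	demo	Pantothenate and CoA biosynthesis	bacterial
CPD0030	Biotin	C10H16N2O3S	244.088163	demo	Biotin metabolism	bacterial
CPD0031	Linoleate	C18H32O2	280.240230	demo	Linoleic acid metabolism|Fatty acid metabolism	plant
CPD0032	Palmitate	C16H32O2	256.240230	demo	Fatty acid biosynthesis|Fatty acid metabolism	mammalian
CPD0033	Oleate	C18H34O2	282.255880	demo	Fatty acid metabolism	plant
CPD0034	Kynurenine	C10H12N2O3	208.084792	demo	Tryptophan metabolism	mammalian
CPD0035	Histamine	C5H9N3	111.079647	demo	Histidine metabolism	mammalian
CPD0036	L-Carnitine	C7H15NO3	161.105193	demo	Lysine degradation	mammalian
CPD0037	Choline	C5H13NO	103.099714	demo	Glycerophospholipid metabolism	mammalian
CPD0038	Betaine	C5H11NO2	117.078979	demo	Glycine, serine and threonine metabolism	plant
CPD0039	Creatinine	C4H7N3O	113.058912	demo	Arginine and proline metabolism	mammalian
CPD0040	Urea	CH4N2O	60.032363	demo	Arginine biosynthesis	mammalian
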