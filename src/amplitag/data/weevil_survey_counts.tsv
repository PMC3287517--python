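sample	otu_id	read_count	closest_match	taxon_class
O_salicicola	JN563736	5516	AB478978 endosymbiont of Pedicinus obtusus / AJ245596 endosymbiont of Camponotus balzanii (Candidatus Blochmannia group)	Gammaproteobacteria
O_salicicola	JN563737	121	DQ417336 Schlegelella aquatica	Betaproteobacteria
O_salicicola	JN563738	96	FJ268988 uncultured Acinetobacter	Gammaproteobacteria
O_salicicola	JN563739	69	CU927677 uncultured bacterium	-
O_salicicola	JN563740	48	FJ534956 uncultured bacterium	-
O_salicicola	JN563741	44	EF210100 Enterobacter hormaechei	Gammaproteobacteria
O_salicicola	JN563742	34	AY923125 Streptococcus sp.	Bacilli
O_salicicola	JN563743	26	EU464962 uncultured bacterium	-
O_salicicola	JN563744	25	EU766013 uncultured bacterium	-
O_salicicola	JN563745	23	FJ393126 uncultured Bacteroides sp.	Bacteroidetes
O_salicicola	JN563746	18	EU721814 uncultured epsilon proteobacterium	Epsilonproteobacteria
O_salicicola	JN563747	17	AY953252 Prevotella sp.	Bacteroidetes
O_salicicola	JN563748	15	FJ799146 bacterium enrichment culture clone LA29	-
O_salicicola	JN563749	11	EU802152 uncultured bacterium	-
O_salicicola	JN563750	10	AY568512 Burkholderia fungorum	Betaproteobacteria
O_rugosostriatus	JN563751	7800	AB021128 Rickettsia sp.	Alphaproteobacteria
O_rugosostriatus	JN563752	396	EF633744 Candidatus Neoehrlichia lotoris	Alphaproteobacteria
O_rugosostriatus	JN563753	338	AB478978 endosymbiont of Pedicinus obtusus / AJ245596 endosymbiont of Camponotus balzanii (Candidatus Blochmannia group)	Gammaproteobacteria
O_rugosostriatus	JN563754	17	AB021128 Rickettsia sp.	Alphaproteobacteria
O_rugosostriatus	JN563755	11	EF633744 Candidatus Neoehrlichia lotoris	Alphaproteobacteria
O_rugosostriatus	JN563756	7	AB021128 Rickettsia sp.	Alphaproteobacteria
O_rugosostriatus	JN563757	6	AB021128 Rickettsia sp.	Alphaproteobacteria
O_rugosostriatus	JN563758	5	FJ868862 uncultured bacterium	-
O_rugosostriatus	JN563759	4	GQ845011 Nevskia sp.	Gammaproteobacteria
O_sulcatus	JN563760	6358	AB021128 Rickettsia sp.	Alphaproteobacteria
O_sulcatus	JN563761	35	EF633744 Candidatus Neoehrlichia lotoris	Alphaproteobacteria
O_sulcatus	JN563762	19	EF633744 Candidatus Neoehrlichia lotoris	Alphaproteobacteria
O_armadillo	JN563763	5900	AB478978 endosymbiont of Pedicinus obtusus / AJ245596 endosymbiont of Camponotus balzanii (Candidatus Blochmannia group)	Gammaproteobacteria
O_armadillo	JN563764	60	FJ823944 uncultured Comamonas sp.	Betaproteobacteria
O_armadillo	JN563765	54	FJ868862 uncultured bacterium	-
O_armadillo	JN563766	43	FJ823944 uncultured Comamonas sp.	Betaproteobacteria
O_armadillo	JN563767	35	FJ544375 Comamonas aquatica	Betaproteobacteria
O_armadillo	JN563768	31	EU560802 uncultured bacterium	-
O_armadillo	JN563769	23	DQ407746 primary endosymbiont of Liposcelis decolor	-
O_armadillo	JN563770	21	DQ469223 uncultured bacterium	-
O_armadillo	JN563771	21	GQ845011 Nevskia sp.	Gammaproteobacteria
O_armadillo	JN563772	20	DQ860049 uncultured bacterium	-
O_armadillo	JN563773	11	AF006670 Shewanella putrefaciens	Gammaproteobacteria
O_armadillo	JN563774	11	X82133 Shewanella putrefaciens	Gammaproteobacteria
O_armadillo	JN563775	11	EU801479 uncultured bacterium	-
O_armadillo	JN563776	10	EF019306 uncultured proteobacterium	-
O_armadillo	JN563777	9	AY953252 Prevotella sp.	Bacteroidetes
O_armadillo	JN563778	8	EU464962 uncultured bacterium	-
O_armadillo	JN563779	8	EU536078 uncultured bacterium	-
O_armadillo	JN563780	8	GQ068015 uncultured bacterium	-
O_armadillo	JN563781	8	L16490 Porphyromonas asaccharolytica	Bacteroidetes
O_armadillo	JN563782	8	AY351787 uncultured marine bacterium	-
O_armadillo	JN563783	6	EF648074 uncultured Azoarcus sp.	Betaproteobacteria
O_armadillo	JN563784	5	EF648074 uncultured Azoarcus sp.	Betaproteobacteria
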