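gene	log_fc	fdr	peak	linkage
2610037D02Rik	-1.38	4.26E-02	Merged-chr15-96084454-1	29,585
6430527G18Rik	0.68	1.33E-02	Merged-chr12-88165302-1	60,462
Arid1b	0.65	7.12E-03	Merged-chr17-4948580-1	46,493
Atp1b2	0.90	2.51E-03	Merged-chr11-69395541-1	23,903
Cat	0.55	2.68E-02	Merged-chr18-65738596-1	Inter (chr2-chr18)
Cat	0.55	2.68E-02	Merged-chr18-65741928-1	Inter (chr2-chr18)
Fnbp1	0.70	1.70E-02	Merged-chr2-30916463-1	81,065
Gm10052	-0.64	7.38E-03	Merged-chr15-88698126-1	Inter (chr9-chr15)
Gm5643	-0.57	2.00E-02	Merged-chr15-88698126-1	Inter (chrX-chr15)
Hnrnpa1	-0.52	4.26E-02	Merged-chr15-88698126-1	14,372,818
Hspb8	0.76	2.59E-02	Merged-chr5-116858161-1	14,712
Jdp2	1.21	1.45E-02	Merged-chr12-86962262-1	21,897
Jdp2	1.21	1.45E-02	Merged-chr12-86961177-1	20,812
Klf5	0.81	2.23E-04	Merged-chr14-99739553-1	41,644
Klf5	0.81	2.23E-04	Merged-chr14-99739095-1	41,186
Npm1	-0.48	4.07E-02	Merged-chr15-97424436-1	Inter (chr11-chr15)
Otx2	-1.90	5.44E-12	Merged-chr14-49274868-1	12,320
Paqr8	1.10	1.31E-02	Merged-chr1-20857728-1	22,969
Ppap2a	0.63	2.62E-02	Merged-chr13-113561150-1	29,951
Ptgfrn	0.62	1.67E-02	Merged-chr3-100967534-1	53,333
Syngr1	0.86	8.95E-04	Merged-chr15-80049889-1	128,116
Tgds	-0.82	3.31E-02	Merged-chr14-49274868-1	69,257,119
Trim59	-0.51	4.26E-02	Merged-chr9-110849737-1	Inter (chr3-chr9)
Tsc22d1	0.77	9.81E-05	Merged-chr14-76915540-1	100,773
Ube2d3	-0.78	9.81E-05	Merged-chr14-20569154-1	Inter (chr3-chr14)
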