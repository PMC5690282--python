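TAF11-TBP
*TAF11 residue*	*TBP residue*	*No. of matches*	*Highest score*
K97	K293	5	9.416
K85	K293	2	8.818
K82	K239	2	8.314
K135	K191	1	8.085
K82	K293	2	7.926
K82	K191	1	7.684
K131	K293	1	6.928
K83	K232	1	6.124
K95	K293	1	4.145
(9 unique links)
TAF13-TBP
*TAF13 residue*	*TBP residue*	*No. of matches*	*Highest score*
K34	K177	1	10.578
K34	K191	1	7.856
K101	K232	1	7.584
K115	K191	1	7.519
K115	K177	1	5.742
(5 unique links)
TAF11-TAF13
*TAF11 residue*	*TAF13 residue*	*No. of matches*	*Highest score*
K195	K96	2	12.795
K85	K101	2	12.014
K204	K96	3	11.053
K89	K101	5	10.98
K204	K101	6	10.909
K131	K34	3	9.627
K82	K92	2	9.321
K197	K96	2	9.308
K131	K111	10	9.226
K135	K111	2	8.371
K131	K115	1	8.326
K207	K92	1	8.292
K82	K96	1	7.981
K85	K115	1	7.943
K94	K101	2	7.934
K97	K101	1	7.867
K204	K92	4	6.872
K85	K92	1	6.817
K82	K101	1	6.437
K206	K92	1	5.77
K204	S74	1	3.42
K206	S74	1	3.42
(22 unique links)
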