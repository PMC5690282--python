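TAF11
*Residues numbers*	*Sequence*	*Δ%D (15 s)*	*Δ%D (120 s)*
93–96	EKKQ	−8.465	−7.309
105–109	KMQIL	−7.014
150–153	VVIA		−7.295
TAF13
*Residues numbers*	*Sequence*	*Δ%D (15 s)*	*Δ%D (120 s)*
14–31	NEEIGGGAEGGQGKRKRL	−7.507	−7.192
32–35	FSKE	−8.794
36–40	LRCMM	−7.0
86–88	IVF	−8.598
86–89	IVFL	−10.366
97–104	FARVKDLL		−7.223
116–124	AFDEANYGS	10.89	8.721
TBP
*Residues numbers*	*Sequence*	*Δ%D (15 s)*	*Δ%D (120 s)*
157–167*	IVPQLQNIVST		9.038
167–174	TVNLGCKL	−9.675	−10.171
193–197	FAAVI	−14.068	−12.267
197–208	IMRIREPRTTAL	−7.785
199–208	RIREPRTTAL	−9.661
209–215	IFSSGKM	−8.655	−8.75
232–244	KYARVVQKLGFPA	−21.337	−18.382
233–242	YARVVQKLGF	−7.128
247–252	LDFKIQ		−7.271
250–256	KIQNMVG	−8.913
259–266	DVKFPIRL	−11.932	−10.109
259–268	DVKFPIRLEG	−13.79	−11.479
260–266	VKFPIRL	−10.393
260–268	VKFPIRLEG	−16.066	−13.002
281–287	PELFPGL		−7.811
285–289	PGLIY	−8.061	−7.339
326–335	PILKGFRKTT	−7.077	−7.902
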