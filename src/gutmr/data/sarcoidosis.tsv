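taxon	level	n_snps	or_ivw	ci_low_ivw	ci_high_ivw	p_ivw	or_wm	ci_low_wm	ci_high_wm	p_wm	or_presso	ci_low_presso	ci_high_presso	p_presso	or_egger	ci_low_egger	ci_high_egger	p_egger
C_Bacilli	class	18	0.77	0.625	0.947	0.013	0.898	0.67	1.201	0.467	0.77	0.638	0.929	0.014	1.439	0.814	2.545	0.229
C_Methanobacteria	class	9	0.818	0.705	0.948	0.008	0.805	0.669	0.97	0.022	0.818	0.728	0.918	0.009	0.895	0.499	1.604	0.720
F_Alcaligenaceae	family	11	0.672	0.508	0.89	0.005	0.815	0.546	1.217	0.317	0.672	0.512	0.884	0.017	1.43	0.396	5.168	0.599
F_Methanobacteriaceae	family	9	0.818	0.705	0.948	0.008	0.805	0.667	0.973	0.025	0.818	0.728	0.918	0.009	0.895	0.499	1.604	0.720
F_Victivallaceae	family	11	1.177	1.008	1.374	0.039	1.165	0.97	1.399	0.101	1.177	1.008	1.374	0.066	0.838	0.408	1.723	0.642
G_Eubacteriumbrachy	genus	10	1.095	0.923	1.3	0.298	1.267	1.038	1.546	0.020	1.095	0.923	1.3	0.325	1.221	0.59	2.527	0.606
G_Eubacteriumruminantium	genus	18	1.154	0.934	1.425	0.185	1.173	0.933	1.473	0.171	1.154	0.934	1.425	0.202	0.444	0.258	0.761	0.009
G_Ruminococcustorques	genus	7	0.603	0.379	0.957	0.032	0.734	0.415	1.299	0.289	0.603	0.379	0.957	0.076	0.328	0.079	1.371	0.187
G_Anaerotruncus	genus	13	1.308	1.019	1.679	0.035	1.288	0.917	1.808	0.144	1.308	1.069	1.601	0.023	1.543	0.743	3.203	0.269
G_Eisenbergiella	genus	11	0.846	0.721	0.992	0.039	0.828	0.669	1.024	0.082	0.846	0.747	0.957	0.024	0.775	0.238	2.526	0.682
G_Erysipelatoclostridium	genus	15	0.801	0.671	0.955	0.014	0.802	0.632	1.016	0.068	0.801	0.686	0.934	0.013	0.733	0.366	1.466	0.396
G_Oscillibacter	genus	12	0.964	0.731	1.272	0.797	1.024	0.779	1.346	0.864	0.964	0.731	1.272	0.802	2.98	1.269	7	0.031
G_Peptococcus	genus	12	1.126	0.973	1.303	0.112	1.238	1.02	1.504	0.031	1.126	0.978	1.296	0.128	0.98	0.558	1.719	0.944
O_Lactobacillales	order	15	0.791	0.629	0.995	0.046	0.895	0.65	1.233	0.498	0.791	0.642	0.975	0.046	1.337	0.739	2.42	0.355
O_Methanobacteriales	order	9	0.818	0.705	0.948	0.008	0.805	0.664	0.978	0.029	0.818	0.728	0.918	0.009	0.895	0.499	1.604	0.720
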