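taxon	level	n_snps	or_ivw	ci_low_ivw	ci_high_ivw	p_ivw	or_wm	ci_low_wm	ci_high_wm	p_wm	or_presso	ci_low_presso	ci_high_presso	p_presso	or_egger	ci_low_egger	ci_high_egger	p_egger
C_Betaproteobacteria	class	8	0.981	0.849	1.134	0.797	0.917	0.796	1.057	0.231	0.981	0.849	1.134	0.805	0.626	0.459	0.855	0.026
C_Erysipelotrichia	class	12	0.997	0.912	1.091	0.950	0.999	0.894	1.116	0.983	0.997	0.912	1.091	0.951	1.552	1.101	2.187	0.031
F_Bacteroidaceae	family	8	1.118	1.016	1.229	0.022	1.174	1.038	1.328	0.011	1.118	1.019	1.225	0.049	0.922	0.528	1.608	0.784
F_Erysipelotrichaceae	family	12	0.997	0.912	1.091	0.950	0.999	0.889	1.123	0.983	0.997	0.912	1.091	0.951	1.552	1.101	2.187	0.031
F_Peptococcaceae	family	8	1.08	1.013	1.151	0.018	1.056	0.97	1.149	0.212	1.08	1.042	1.118	0.004	1.097	0.946	1.273	0.266
G_Bacteroides	genus	8	1.118	1.016	1.229	0.022	1.174	1.033	1.333	0.014	1.118	1.019	1.225	0.049	0.922	0.528	1.608	0.784
G_Catenibacterium	genus	5	1.057	1.002	1.114	0.042	1.036	0.966	1.11	0.324	1.057	1.016	1.099	0.052	1.19	0.727	1.949	0.538
G_Coprococcus2	genus	7	0.919	0.846	1	0.049	0.919	0.825	1.025	0.130	0.919	0.88	0.961	0.010	0.805	0.419	1.546	0.543
G_Defluviitaleaceae	genus	8	1.076	1.01	1.145	0.023	1.058	0.978	1.145	0.161	1.076	1.034	1.119	0.008	1.004	0.81	1.243	0.975
G_Flavonifractor	genus	4	0.887	0.769	1.023	0.098	0.865	0.754	0.992	0.037	0.887	0.769	1.023	0.197	1.176	0.697	1.983	0.605
G_Haemophilus	genus	8	0.925	0.874	0.98	0.008	0.906	0.837	0.98	0.014	0.925	0.874	0.98	0.033	0.838	0.742	0.947	0.030
G_Lachnoclostridium	genus	8	1.173	1.045	1.316	0.007	1.165	1.017	1.334	0.027	1.173	1.045	1.316	0.030	0.921	0.635	1.336	0.681
G_Oscillospira	genus	6	0.91	0.837	0.99	0.029	0.913	0.815	1.022	0.115	0.91	0.837	0.99	0.079	1.045	0.726	1.505	0.824
G_RuminococcaceaeUCG003	genus	12	0.993	0.908	1.086	0.880	0.895	0.803	0.997	0.043	0.993	0.908	1.086	0.882	0.844	0.639	1.116	0.262
G_RuminococcaceaeUCG014	genus	9	1.091	1.013	1.174	0.021	1.056	0.953	1.171	0.300	1.091	1.026	1.159	0.024	1.022	0.853	1.225	0.821
O_Bacillales	order	6	0.938	0.895	0.984	0.008	0.925	0.871	0.983	0.011	0.938	0.901	0.977	0.028	0.84	0.688	1.026	0.163
O_Burkholderiales	order	8	0.981	0.85	1.132	0.793	0.917	0.797	1.055	0.224	0.981	0.85	1.132	0.800	0.634	0.464	0.865	0.028
O_Erysipelotrichales	order	12	0.997	0.912	1.091	0.950	0.999	0.891	1.12	0.983	0.997	0.912	1.091	0.951	1.552	1.101	2.187	0.031
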