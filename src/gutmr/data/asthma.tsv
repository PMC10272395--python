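taxon	level	n_snps	or_ivw	ci_low_ivw	ci_high_ivw	p_ivw	or_wm	ci_low_wm	ci_high_wm	p_wm	or_presso	ci_low_presso	ci_high_presso	p_presso	or_egger	ci_low_egger	ci_high_egger	p_egger
C_Bacteroidia	class	8	1.077	0.989	1.172	0.088	1.122	1.012	1.243	0.028	1.077	0.989	1.172	0.132	1.094	0.837	1.43	0.534
C_Clostridia	class	10	0.898	0.819	0.986	0.023	0.97	0.889	1.058	0.489	0.898	0.819	0.986	0.049	0.739	0.471	1.161	0.226
C_Gammaproteobacteria	class	4	1.15	1.049	1.26	0.003	1.143	1.024	1.276	0.018	1.15	1.112	1.189	0.004	1.4	0.749	2.62	0.402
F_Lachnospiraceae	family	16	1.079	1.018	1.143	0.010	1.061	0.989	1.139	0.097	1.079	1.018	1.143	0.021	1.103	0.944	1.288	0.238
F_Oxalobacteraceae	family	12	0.976	0.939	1.014	0.218	0.993	0.949	1.039	0.762	0.976	0.939	1.014	0.243	1.171	1.039	1.32	0.027
F_Pasteurellaceae	family	11	0.958	0.925	0.992	0.015	0.957	0.912	1.004	0.070	0.958	0.934	0.982	0.007	0.993	0.922	1.069	0.855
F_Rikenellaceae	family	13	0.936	0.878	0.998	0.043	0.951	0.879	1.03	0.218	0.936	0.878	0.998	0.066	0.993	0.806	1.224	0.951
F_Streptococcaceae	family	10	0.984	0.912	1.062	0.679	0.973	0.898	1.055	0.511	0.984	0.912	1.062	0.688	0.68	0.539	0.859	0.012
G_Anaerofilum	genus	10	0.967	0.927	1.01	0.131	0.947	0.902	0.994	0.029	0.967	0.927	1.01	0.165	0.856	0.686	1.069	0.208
G_Haemophilus	genus	8	0.958	0.921	0.996	0.032	0.967	0.918	1.018	0.200	0.958	0.937	0.98	0.007	0.956	0.877	1.042	0.347
G_Holdemania	genus	14	0.985	0.942	1.029	0.492	0.999	0.95	1.051	0.982	0.985	0.942	1.029	0.504	1.134	1.022	1.259	0.036
G_Ruminiclostridium5	genus	8	0.868	0.811	0.931	6.241E-5	0.89	0.81	0.978	0.015	0.868	0.811	0.931	0.005	0.693	0.536	0.897	0.032
O_Bacillales	order	6	0.977	0.923	1.034	0.417	0.937	0.896	0.98	0.004	0.977	0.923	1.034	0.454	0.822	0.673	1.004	0.127
O_Bacteroidales	order	8	1.077	0.989	1.172	0.088	1.122	1.021	1.233	0.017	1.077	0.989	1.172	0.132	1.094	0.837	1.43	0.534
O_Lactobacillales	order	12	0.93	0.885	0.977	0.004	0.945	0.878	1.018	0.135	0.93	0.885	0.977	0.014	0.848	0.753	0.956	0.023
O_NB1n	order	12	1.064	1.032	1.096	5.821E-5	1.043	1	1.089	0.052	1.064	1.032	1.096	0.002	1.056	0.927	1.204	0.431
O_Pasteurellales	order	11	0.958	0.925	0.992	0.015	0.957	0.912	1.004	0.070	0.958	0.934	0.982	0.007	0.993	0.922	1.069	0.855
P_Bacteroidetes	phylum	8	1.096	1.011	1.187	0.025	1.123	1.022	1.234	0.016	1.096	1.011	1.187	0.060	1.039	0.81	1.331	0.775
P_Proteobacteria	phylum	10	0.973	0.909	1.041	0.429	0.967	0.892	1.048	0.411	0.973	0.909	1.041	0.449	0.807	0.685	0.951	0.034
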