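taxon	level	n_snps	or_ivw	ci_low_ivw	ci_high_ivw	p_ivw	or_wm	ci_low_wm	ci_high_wm	p_wm	or_presso	ci_low_presso	ci_high_presso	p_presso	or_egger	ci_low_egger	ci_high_egger	p_egger
C_Erysipelotrichia	class	13	0.393	0.172	0.901	0.027	0.406	0.143	1.153	0.090	0.393	0.172	0.901	0.048	0.029	0.001	0.806	0.061
F_Alcaligenaceae	family	11	2.394	1.17	4.896	0.017	2.909	1.124	7.531	0.028	2.394	1.3	4.408	0.019	2.105	0.079	56.139	0.667
F_Erysipelotrichaceae	family	13	0.393	0.172	0.901	0.027	0.406	0.149	1.101	0.077	0.393	0.172	0.901	0.048	0.029	0.001	0.806	0.061
G_Eubacteriumrectale	genus	8	0.414	0.149	1.149	0.090	0.279	0.084	0.929	0.038	0.414	0.149	1.149	0.134	11.209	0.579	217.15	0.161
G_Catenibacterium	genus	4	0.518	0.305	0.879	0.015	0.57	0.298	1.093	0.091	0.518	0.386	0.695	0.022	0.979	0.001	741.033	0.995
G_Gordonibacter	genus	11	1.224	0.877	1.707	0.235	1.545	1.003	2.382	0.049	1.224	0.902	1.659	0.223	1.403	0.343	5.748	0.649
G_Lachnospiraceae	genus	10	0.793	0.484	1.3	0.358	0.518	0.275	0.979	0.043	0.793	0.484	1.3	0.382	7.685	0.772	76.458	0.120
G_Ruminococcus1	genus	10	0.471	0.228	0.973	0.042	0.763	0.294	1.976	0.577	0.471	0.228	0.973	0.073	1.063	0.151	7.488	0.953
G_Slackia	genus	6	1.717	0.941	3.134	0.078	2.184	1.009	4.723	0.047	1.717	1.019	2.894	0.098	1.825	0.037	89.29	0.777
O_Erysipelotrichales	order	13	0.393	0.172	0.901	0.027	0.406	0.147	1.121	0.082	0.393	0.172	0.901	0.048	0.029	0.001	0.806	0.061
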