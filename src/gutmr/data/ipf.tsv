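taxon	level	n_snps	or_ivw	ci_low_ivw	ci_high_ivw	p_ivw	or_wm	ci_low_wm	ci_high_wm	p_wm	or_presso	ci_low_presso	ci_high_presso	p_presso	or_egger	ci_low_egger	ci_high_egger	p_egger
C_Coriobacteriia	class	13	0.763	0.602	0.968	0.026	0.75	0.554	1.016	0.063	0.763	0.602	0.968	0.046	0.396	0.156	1.006	0.078
F_Acidaminococcaceae	family	5	0.735	0.552	0.979	0.035	0.771	0.547	1.087	0.138	0.735	0.552	0.979	0.103	0.531	0.21	1.346	0.275
F_Coriobacteriaceae	family	13	0.763	0.602	0.968	0.026	0.75	0.547	1.028	0.074	0.763	0.602	0.968	0.046	0.396	0.156	1.006	0.078
F_familyXIII	family	10	0.782	0.613	0.998	0.048	0.784	0.577	1.065	0.120	0.782	0.665	0.92	0.016	0.825	0.359	1.894	0.662
G_Ruminococcusgnavus	genus	7	0.792	0.629	0.996	0.046	0.864	0.678	1.1	0.235	0.792	0.629	0.996	0.093	0.637	0.226	1.79	0.431
G_Blautia	genus	10	1.269	1.029	1.565	0.026	1.362	1.017	1.825	0.038	1.269	1.033	1.558	0.049	1.181	0.763	1.827	0.476
G_Eisenbergiella	genus	10	1.232	1.075	1.412	0.003	1.23	1.024	1.478	0.027	1.232	1.09	1.393	0.009	0.983	0.36	2.682	0.974
G_Holdemania	genus	14	1.271	1.095	1.476	0.002	1.208	0.985	1.481	0.069	1.271	1.095	1.476	0.008	1.127	0.724	1.756	0.606
G_Hungatella	genus	3	0.778	0.629	0.962	0.021	0.801	0.609	1.055	0.114	NA	NA	NA	NA	1.377	0.399	4.747	0.702
O_Coriobacteriales	order	13	0.763	0.602	0.968	0.026	0.75	0.547	1.029	0.074	0.763	0.602	0.968	0.046	0.396	0.156	1.006	0.078
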