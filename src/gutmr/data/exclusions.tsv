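outcome	taxon	reason
copd	C_Betaproteobacteria	pleiotropy
copd	C_Erysipelotrichia	pleiotropy
copd	F_Erysipelotrichaceae	pleiotropy
copd	O_Burkholderiales	pleiotropy
copd	O_Erysipelotrichales	pleiotropy
copd	G_Flavonifractor	loo_inconsistent
copd	G_RuminococcaceaeUCG003	loo_inconsistent
asthma	P_Proteobacteria	pleiotropy
asthma	C_Clostridia	pleiotropy
asthma	O_Bacillales	pleiotropy
asthma	F_Oxalobacteraceae	pleiotropy
asthma	F_Streptococcaceae	pleiotropy
asthma	G_Holdemania	pleiotropy
asthma	C_Bacteroidia	loo_inconsistent
asthma	O_Bacteroidales	loo_inconsistent
asthma	G_Anaerofilum	loo_inconsistent
sarcoidosis	C_Bacilli	pleiotropy_or_heterogeneity
sarcoidosis	G_Eubacteriumruminantium	pleiotropy_or_heterogeneity
sarcoidosis	G_Oscillibacter	pleiotropy_or_heterogeneity
sarcoidosis	G_Eubacteriumbrachy	loo_inconsistent
sarcoidosis	G_Peptococcus	loo_inconsistent
pneumoconiosis	G_Eubacteriumrectale	loo_inconsistent
pneumoconiosis	G_Gordonibacter	loo_inconsistent
pneumoconiosis	G_Lachnospiraceae	loo_inconsistent
pneumoconiosis	G_Slackia	loo_inconsistent
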