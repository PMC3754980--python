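cluster	mz	presence	match	correlated_matches
1	186.221	Higher	No Match	Pentachlorochyclohexanol; pentachlorodibenzodioxin; tripeptides; modified amino acids
1	208.096	Higher	Acetylphenylalanine	Acetyltryptophan; features from Cluster
1	310.187	Higher	Dipeptide; Tripeptides	Modified cysteine and alanine acids
1	328.192	Higher	Sethoxydim (herbicide)	Tripeptides
1	341.192	Higher	Tripeptides	Acetyltryptophan; features from Cluster
1	341.192	Higher	Tripeptides	No Matches
1	344.184	Higher	Tripeptides	Acetyltryptophan
1	353.103	Higher	Flavones; halofenozide	Pentachlorochyclohexanol, pentachlorodibenzodioxin
2	448.303	Lower	Glycocholic acid	Features from Cluster 2
2	449.306	Lower	Vitamin D-related metabolites; phytochemicals	Features from Cluster 2
2	450.318	Lower	Glycodeoxycholic acid+H+; Glycoursodeoxycholic acid+H+	Vitamin D-related metabolites; ions derived from sphingofungin A; terpenoid; features from Cluster
2	472.300	Lower	Glycodeoxycholic acid+Na+; Glycoursodeoxycholic acid+Na+	Vitamin D-related metabolites; ions derived from sphingofungin A; terpenoid; features from Cluster
2	656.792	Lower	No Match	Phytochemicals; glutamate metabolites
3	244.189	Lower	No Match	Feature from Cluster; one unmatched feature
3	245.193	Lower	Senecrassidiol	Feature from Cluster; one unmatched feature
4	328.137	Lower	Didemethylsimmondsin	Feature from Cluster
4	334.157	Lower	Dipeptides	Feature from Cluster
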