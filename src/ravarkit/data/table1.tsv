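study_id	variant_id	risk_allele	p_value	odds_ratio	n_cases	n_controls	population	coverage	design	phenotype_note	locus_id
Hu2011	rs805297	A	6.65e-005	1.40	578	711	East Asian	selected	followup		APOM
Padyukov2011	rs805297	A	1.49e-016	.	1147	1079	European	genome_wide	gwas		APOM
Okada2012	rs3093023	A	2.1e-017	1.27	4074	16891	East Asian	genome_wide	gwas		CCR6
Stahl2010	rs3093023	A	1.5e-011	1.12	12307	28975	European	genome_wide	gwas		CCR6
Li2012	rs231775	G	0.01	1.45	199	199	Central American	selected	followup		CTLA4_ICOS
Li2012	rs231775	G	0.002	1.18	2734	1441	East Asian	selected	followup	Selected (Meta)	CTLA4_ICOS
Plant2010	rs231775	.	0.009	1.07	6160	6684	European	selected	followup	Selected (Meta)	CTLA4_ICOS
Kochi2010	rs13192471	G	1.9e-058	1.97	2303	3380	East Asian	genome_wide	gwas		HLA-DRB1
Prasad2012	rs13192471	G	6.7e-016	2.16	983	1007	South Asian	selected	followup		HLA-DRB1
Okada2012	rs2157337	C	2.6e-118	1.99	4074	16891	East Asian	genome_wide	gwas		HLA-DRB1
Stahl2010	rs2157337	C	1e-299	2.50	5539	20169	European	genome_wide	gwas		HLA-DRB1
Terao2011	rs2516049	C	3.6e-031	2.18	874	855	East Asian	genome_wide	gwas		HLA-DRB1
Padyukov2011	rs2516049	C	1.64e-042	.	1147	1079	European	genome_wide	gwas		HLA-DRB1
WTCCC2007	rs6457617	T	3.44e-076	.	1861	2938	European	genome_wide	gwas		HLA-DRB1
Prasad2012	rs6457617	A	1.6e-009	1.48	983	1007	South Asian	selected	followup		HLA-DRB1
Padyukov2011	rs660895	G	5.83e-053	.	1147	1079	European	genome_wide	gwas		HLA-DRB1
Prasad2012	rs660895	G	2.56e-005	1.52	983	1007	South Asian	selected	followup		HLA-DRB1
Stahl2010	rs6910071	G	1e-299	2.88	5539	20169	European	genome_wide	gwas		HLA-DRB1
Prasad2012	rs6910071	.	0.04	1.27	983	1007	South Asian	selected	followup		HLA-DRB1
Kurreeman2012	rs2872507	G	0.006	0.79	440	795	African American	selected	followup		IKZF3
Kurreeman2012	rs2872507	G	0.003	0.91	2414	14245	East Asian	selected	followup		IKZF3
Stahl2010	rs2872507	A	9.4e-007	1.09	12307	28975	European	genome_wide	gwas		IKZF3
Stahl2010	rs13119723	G	6.8e-007	0.88	12307	28975	European	genome_wide	gwas		IL2_IL21
Prasad2012	rs13119723	G	0.008	0.75	983	1007	South Asian	selected	followup		IL2_IL21
Plant2010	rs6822844	.	5.89e-008	0.88	12953	13370	European	selected	followup	Selected (Meta)	IL2_IL21
Maiti2010	rs6822844	.	0.019	0.61	354	368	South American	selected	followup		IL2_IL21
Plant2010	rs2104286	.	2.48e-05	0.91	10112	10450	European	selected	followup	Selected (Meta)	IL2RA
Prasad2012	rs2104286	G	0.00019	0.73	983	1007	South Asian	selected	followup		IL2RA
Lee2012	rs1800795	G	1e-008	0.074	120	168	East Asian	selected	followup		IL6
Lee2012	rs1800795	G	7.4e-005	0.46	425	247	West Asian	selected	followup		IL6
Lee2012	rs2230926	.	0.032	1.84	7148	1513	African American	selected	followup		OLIG3_TNFAIP3
Kochi2010	rs2230926	C	1.6e-006	1.31	7069	15876	East Asian	genome_wide	gwas		OLIG3_TNFAIP3
Okada2012	rs5029937	T	3.9e-009	1.33	4074	16891	East Asian	genome_wide	gwas		OLIG3_TNFAIP3
Plant2010	rs5029937	.	4.62e-010	1.42	7731	9403	European	selected	followup	Selected (Meta)	OLIG3_TNFAIP3
Okada2012	rs934734	G	3.2e-007	1.19	4074	16891	East Asian	genome_wide	gwas		SPRED2
Stahl2010	rs934734	G	5.3e-010	1.13	12307	28975	European	genome_wide	gwas		SPRED2
Kochi2010	rs7574865	T	1.8e-006	1.17	7069	15876	East Asian	genome_wide	gwas		STAT4
Plant2010	rs7574865	.	2.99e-015	1.18	14394	16131	European	selected	followup	Selected (Meta)	STAT4
Kurreeman2012	rs2793108	T	0.001	1.11	2414	14245	East Asian	selected	followup		ZEB1
Prasad2012	rs2793108	C	0.006	0.84	983	1007	South Asian	selected	followup		ZEB1
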