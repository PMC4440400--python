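# Published efficiency values (percent) and CO2:TEA yields for the strain
# compilation, used to report deviations of the recomputed values.
id	eps_I_pct	eps_II_pct	eps_so_min_pct	co2_tea
thiobacillus_denitrificans_a1	6.39	17.59	22.76	0.41
thiobacillus_denitrificans_a2	5.50	15.13	19.58	0.35
thiothrix_ct3	5.55	15.29	19.78	0.36
beggiatoa_d402	4.91	13.52	17.50	0.31
thermothrix_thiopara	4.34	11.93	15.44	0.28
thermithiobacillus_tepidarius_thio	3.81	10.50	13.58	0.24
thioalkalivibrio_versutus	2.90	7.96	10.30	0.18
acidithiobacillus_ferrooxidans	2.80	7.72	9.99	0.18
paracoccus_versutus	2.70	7.42	9.60	0.17
halothiobacillus_neapolitanus_thio	2.57	7.07	9.15	0.16
thiomicrospira_thioparus	2.48	6.84	8.85	0.16
sulfurimonas_denitrificans_aer	3.13	7.99	8.18	0.20
acidithiobacillus_thiooxidans	2.26	6.21	8.03	0.14
halothiobacillus_halophilus	2.23	6.15	7.96	0.14
thiothrix_ramosa	2.23	6.15	7.96	0.14
thioalkalispira_microaerophila	2.05	5.65	7.31	0.13
thioalkalimicrobium_aerophilum	1.91	5.27	6.82	0.12
thiomicrospira_halophila	1.91	5.27	6.82	0.12
thioalkalibacter_halophilus	1.91	5.27	6.82	0.12
thiobacillus_thioparus	1.78	4.89	6.33	0.11
thioclava_pacifica	1.49	4.10	5.31	0.10
thioalkalimicrobium_sibericum	1.43	3.95	5.11	0.09
thiomicrospira_l12	1.29	3.91	4.99	0.09
thiobacillus_denitrificans_d1	5.15	14.18	18.35	0.36
thiobacillus_denitrificans_d2	4.11	11.31	14.63	0.29
sulfurimonas_hongkongensis	3.08	7.85	8.04	0.22
sulfurimonas_gotlandica	2.53	6.45	6.61	0.18
sulfurimonas_gotlandica_like	2.26	5.76	5.89	0.16
sulfurimonas_denitrificans_den	1.93	4.91	5.03	0.14
riftia_symbionts_1	30.52	77.27	98.86	1.67
solemya_reidi_symbionts	22.83	59.80	76.87	1.33
riftia_symbionts_2	16.80	44.50	57.29	1.00
beggiatoa_ms81_1c	9.72	25.30	32.50	0.56
ridgeia_piscesae_symbionts	6.98	18.13	23.29	0.40
thermithiobacillus_tepidarius_sulf	4.14	10.76	13.81	0.24
beggiatoa_ms81_6	3.70	9.60	12.33	0.21
halothiobacillus_neapolitanus_sulf	2.86	7.43	9.54	0.16
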