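# Literature-derived stoichiometric parameters of cultivated sulfur oxidizers:
# S0 partition x, energy fraction y, substrate, terminal acceptor process and
# CO2 fixation pathway. Symbiont rows assume the Calvin cycle. The source
# column carries the literature reference tag of the compilation.
id	name	group	substrate	tea	pathway	x	y	source
thiobacillus_denitrificans_a1	Thiobacillus denitrificans	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.710	refs_1-6
thiobacillus_denitrificans_a2	Thiobacillus denitrificans	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.740	refs_1-6
thiothrix_ct3	Thiothrix CT3	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.738	ref_7
beggiatoa_d402	Beggiatoa str. D-402	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.761	ref_8
thermothrix_thiopara	Thermothrix thiopara	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.783	refs_9-10
thermithiobacillus_tepidarius_thio	Thermithiobacillus tepidarius	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.804	refs_5-11-12
thioalkalivibrio_versutus	Thioalkalivibrio versutus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.844	refs_13-14
acidithiobacillus_ferrooxidans	Acidithiobacillus ferrooxidans	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.848	refs_3-16-18
paracoccus_versutus	Paracoccus versutus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.853	refs_10-15
halothiobacillus_neapolitanus_thio	Halothiobacillus neapolitanus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.859	refs_3-19-20
thiomicrospira_thioparus	Thiomicrospira thioparus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.863	refs_20-21
sulfurimonas_denitrificans_aer	Sulfurimonas denitrificans	aerobic_thiosulfate	thiosulfate	aerobic	rtca	0	0.833	refs_6-39-40
acidithiobacillus_thiooxidans	Acidithiobacillus thiooxidans	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.874	refs_10-22-24
halothiobacillus_halophilus	Halothiobacillus halophilus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.875	refs_25-27
thiothrix_ramosa	Thiothrix ramosa	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.875	refs_5-28
thioalkalispira_microaerophila	Thioalkalispira microaerophila	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.884	refs_14-29
thioalkalimicrobium_aerophilum	Thioalkalimicrobium aerophilum	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.891	ref_13
thiomicrospira_halophila	Thiomicrospira halophila	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.891	refs_5-30
thioalkalibacter_halophilus	Thioalkalibacter halophilus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.891	refs_5-31
thiobacillus_thioparus	Thiobacillus thioparus	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.898	refs_5-17-32-36
thioclava_pacifica	Thioclava pacifica	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.913	ref_37
thioalkalimicrobium_sibericum	Thioalkalimicrobium sibericum	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0	0.916	ref_13
thiomicrospira_l12	Thiomicrospira sp. strain L-12	aerobic_thiosulfate	thiosulfate	aerobic	calvin	0.2	0.921	refs_38-39
thiobacillus_denitrificans_d1	Thiobacillus denitrificans	denitrifying_thiosulfate	thiosulfate	denitrification	calvin	0	0.775	refs_1-4-6
thiobacillus_denitrificans_d2	Thiobacillus denitrificans	denitrifying_thiosulfate	thiosulfate	denitrification	calvin	0	0.812	ref_40
sulfurimonas_hongkongensis	Sulfurimonas hongkongensis	denitrifying_thiosulfate	thiosulfate	denitrification	rtca	0	0.852	ref_41
sulfurimonas_gotlandica	Sulfurimonas gotlandica	denitrifying_thiosulfate	thiosulfate	denitrification	rtca	0	0.875	refs_42-43
sulfurimonas_gotlandica_like	Sulfurimonas gotlandica-like epsilonproteobacterium	denitrifying_thiosulfate	thiosulfate	denitrification	rtca	0	0.887	refs_43-44
sulfurimonas_denitrificans_den	Sulfurimonas denitrificans	denitrifying_thiosulfate	thiosulfate	denitrification	rtca	0	0.902	refs_6-45
riftia_symbionts_1	Riftia pachyptila symbionts	aerobic_sulfide	sulfide	aerobic	calvin	-1.12	0.375	refs_46-48
solemya_reidi_symbionts	Solemya reidi symbionts	aerobic_sulfide	sulfide	aerobic	calvin	0.17	0.429	refs_49-50
riftia_symbionts_2	Riftia pachyptila symbionts	aerobic_sulfide	sulfide	aerobic	calvin	0.33	0.500	refs_5-46-48-51
beggiatoa_ms81_1c	Beggiatoa str. MS-81-1c	aerobic_sulfide	sulfide	aerobic	calvin	0.05	0.641	ref_52
ridgeia_piscesae_symbionts	Ridgeia piscesae symbionts	aerobic_sulfide	sulfide	aerobic	calvin	0	0.714	ref_53
thermithiobacillus_tepidarius_sulf	Thermithiobacillus tepidarius	aerobic_sulfide	sulfide	aerobic	calvin	0	0.808	refs_12-54
beggiatoa_ms81_6	Beggiatoa str. MS-81-6	aerobic_sulfide	sulfide	aerobic	calvin	0	0.825	ref_52
halothiobacillus_neapolitanus_sulf	Halothiobacillus neapolitanus	aerobic_sulfide	sulfide	aerobic	calvin	0	0.859	refs_20-53-51
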