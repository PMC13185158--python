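# RhlB (426 aa) binding-site configuration: docking-derived and motif-predicted
# residue positions with ligand class, interaction notes and docking scores.
# Product (M-RL) sites are annotation only and never trigger exclusion.
pos	ligand	source	note	ac_score	swissparam_score
228	substrate_lipid	docking	HAAs long loop p225-240, multiple H-bonds with carboxyl groups	-66.36	-6.8
229	substrate_lipid	docking	HAAs long loop p225-240, multiple H-bonds with carboxyl groups	-66.36	-6.8
231	substrate_lipid	docking	HAAs long loop p225-240, multiple H-bonds with carboxyl groups	-66.36	-6.8
233	substrate_lipid	docking	HAAs long loop p225-240, multiple H-bonds with carboxyl groups	-66.36	-6.8
330	substrate_lipid	docking	HAAs 13th alpha-helix p325-333, one H-bond	-66.36	-6.8
9	substrate_sugar	docking	dTDP-L-rhamnose short loop p7-13, H-bond	-314.62	-9.81
10	substrate_sugar	docking	dTDP-L-rhamnose short loop p7-13, H-bond	-314.62	-9.81
13	substrate_sugar	docking	dTDP-L-rhamnose short loop p7-13, H-bond + ionic bond	-314.62	-9.81
231	substrate_sugar	docking	dTDP-L-rhamnose long loop p225-240, hydrophobic bond	-314.62	-9.81
259	substrate_sugar	docking	dTDP-L-rhamnose medium loop p258-266, 1 H-bond	-314.62	-9.81
260	substrate_sugar	docking	dTDP-L-rhamnose medium loop p258-266, 3 H-bonds	-314.62	-9.81
306	substrate_sugar	docking	dTDP-L-rhamnose alpha-turn p305-308, hydrophobic bond	-314.62	-9.81
309	substrate_sugar	docking	dTDP-L-rhamnose 12th alpha-helix p309-315, hydrophobic bond	-314.62	-9.81
324	substrate_sugar	docking	dTDP-L-rhamnose beta-turn p322-324, H-bond	-314.62	-9.81
325	substrate_sugar	docking	dTDP-L-rhamnose 13th alpha-helix p325-333, H-bond	-314.62	-9.81
346	substrate_sugar	docking	dTDP-L-rhamnose short loop p341-346, H-bond	-314.62	-9.81
347	substrate_sugar	docking	dTDP-L-rhamnose 14th alpha-helix p347-357, H-bond	-314.62	-9.81
396	product	docking	M-RL primary site, 2 H-bonds with ligand + 1 with structure	-32.05	-7.4
333	product	docking	M-RL primary site, hydrophobic bond with ligand and structure	-32.05	-7.4
22	product	docking	M-RL primary site, ionic bond	-32.05	-7.4
230	product	docking	M-RL primary site, hydrophobic bond	-32.05	-7.4
11	product	docking	M-RL secondary site	-30.6	-9.034
15	product	docking	M-RL secondary site	-30.6	-9.034
260	product	docking	M-RL secondary site	-30.6	-9.034
286	product	docking	M-RL secondary site	-30.6	-9.034
306	product	docking	M-RL secondary site	-30.6	-9.034
309	product	docking	M-RL secondary site	-30.6	-9.034
326	product	docking	M-RL secondary site	-30.6	-9.034
10	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
13	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
260	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
306	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
346	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
347	atp	docking	shared ATP/dTDP-L-rhamnose docking contact
263	atp	motif	anchor residue in loop between beta8 and alpha11, putative ATP site
305	atp	motif	alpha-turn AYAP p305-308 ATP site
306	atp	motif	alpha-turn AYAP p305-308 ATP site
307	atp	motif	alpha-turn AYAP p305-308 ATP site, anchor residue
308	atp	motif	alpha-turn AYAP p305-308 ATP site
321	gtp	motif	beta-turn PGG p321-324 GTP site
322	gtp	motif	beta-turn PGG p321-324 GTP site
323	gtp	motif	beta-turn PGG p321-324 GTP site
324	gtp	motif	beta-turn PGG p321-324 GTP site
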