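id	full_name	family	formula	mw	cmc_mM	smiles	monomer_volume_A3	volume_source	reference	aliases	color
DDM	n-dodecyl-beta-D-maltopyranoside	maltoside	C24H46O11	510.62	0.17	CCCCCCCCCCCCOC1OC(CO)C(OC2OC(CO)C(O)C(O)C2O)C(O)C1O	495.7	additive_estimate	Anatrace product data; VanAken et al. Methods Enzymol 1986	b-DDM|dodecyl maltoside|C12M	0.2,0.7,0.3
DM	n-decyl-beta-D-maltopyranoside	maltoside	C22H42O11	482.57	1.8	CCCCCCCCCCOC1OC(CO)C(OC2OC(CO)C(O)C(O)C2O)C(O)C1O	461.1	additive_estimate	Anatrace product data	decyl maltoside|C10M	0.2,0.7,0.3
OG	n-octyl-beta-D-glucopyranoside	glucoside	C14H28O6	292.37	19	CCCCCCCCOC1OC(CO)C(O)C(O)C1O	291.1	additive_estimate	Lorber et al. BBA 1990	b-OG|octyl glucoside	0.9,0.6,0.1
NG	n-nonyl-beta-D-glucopyranoside	glucoside	C15H30O6	306.4	6.5	CCCCCCCCCOC1OC(CO)C(O)C(O)C1O	308.4	additive_estimate	Anatrace product data	nonyl glucoside	0.9,0.6,0.1
LMNG	lauryl maltose neopentyl glycol	neopentyl glycol	C47H88O22	1005.2	0.01	CCCCCCCCCCC(CCCCCCCCCC)(COC1OC(CO)C(OC2OC(CO)C(O)C(O)C2O)C(O)C1O)COC3OC(CO)C(OC4OC(CO)C(O)C(O)C4O)C(O)C3O	965.6	additive_estimate	Chae et al. Nat Methods 2010	MNG-3|lauryl maltose neopentyl glycol	0.95,0.5,0.7
DMNG	decyl maltose neopentyl glycol	neopentyl glycol	C43H80O22	949.09	0.036	CCCCCCCCC(CCCCCCCC)(COC1OC(CO)C(OC2OC(CO)C(O)C(O)C2O)C(O)C1O)COC3OC(CO)C(OC4OC(CO)C(O)C(O)C4O)C(O)C3O	896.4	additive_estimate	Chae et al. Nat Methods 2010	MNG-2	0.95,0.5,0.7
CHS	cholesteryl hemisuccinate	cholesterol derivative	C31H50O4	486.74		CC(C)CCCC(C)C1CCC2C1(C)CCC3C2CC=C4CC(OC(=O)CCC(O)=O)CCC34C	522.7	additive_estimate	Anatrace product data	cholesterol hemisuccinate	0.6,0.4,0.2
FC-12	n-dodecylphosphocholine (fos-choline-12)	fos-choline	C17H38NO4P	351.47	1.5	CCCCCCCCCCCCOP(=O)([O-])OCC[N+](C)(C)C	369.1	additive_estimate	Anatrace product data	DPC|fos-choline 12	0.3,0.5,0.9
LDAO	n-dodecyl-N,N-dimethylamine-N-oxide	amine oxide	C14H31NO	229.41	1	CCCCCCCCCCCC[N+](C)(C)[O-]	270.6	additive_estimate	Herrmann J Colloid Interface Sci 1962	DDAO|lauryldimethylamine oxide	0.5,0.3,0.8
OTG	n-octyl-beta-D-thioglucopyranoside	thio-derivative	C14H28O5S	308.44	9	CCCCCCCCSC1OC(CO)C(O)C(O)C1O	300.9	additive_estimate	Saito & Tsuchiya Biochem J 1984	octyl thioglucoside	0.8,0.8,0.2
DDTM	n-dodecyl-beta-D-thiomaltopyranoside	thio-derivative	C24H46O10S	526.69	0.05	CCCCCCCCCCCCSC1OC(CO)C(OC2OC(CO)C(O)C(O)C2O)C(O)C1O	505.4	additive_estimate	Anatrace product data	dodecyl thiomaltoside	0.8,0.8,0.2
CHOLATE	sodium cholate	bile salt	C24H40O5	408.58	14	CC(CCC(O)=O)C1CCC2C1(C)C(O)CC3C2C(O)CC4CC(O)CCC34C	415.6	additive_estimate	Reynolds Methods Enzymol 1986	NaC|cholic acid	0.2,0.7,0.7
POPC	1-palmitoyl-2-oleoyl-sn-glycero-3-phosphocholine	lipid	C42H82NO8P	760.09		CCCCCCCCCCCCCCCC(=O)OCC(COP(=O)([O-])OCC[N+](C)(C)C)OC(=O)CCCCCCCC=CCCCCCCCC	828.8	additive_estimate	Avanti Polar Lipids data	palmitoyl-oleoyl-PC	0.45,0.45,0.45
DMPC	1,2-dimyristoyl-sn-glycero-3-phosphocholine	lipid	C36H72NO8P	677.94		CCCCCCCCCCCCCC(=O)OCC(COP(=O)([O-])OCC[N+](C)(C)C)OC(=O)CCCCCCCCCCCCC	727.7	additive_estimate	Avanti Polar Lipids data	dimyristoyl-PC	0.45,0.45,0.45
A8-35	amphipol A8-35	amphipol	(C228H408N24O50)avg	4286		CC(CC(CC(C)C(O)=O)C(=O)NCCCCCCCC)C(=O)NC(C)C	4558.8	additive_estimate	Tribet et al. PNAS 1996 (average chain composition)	A835|amphipol	0.7,0.2,0.2
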