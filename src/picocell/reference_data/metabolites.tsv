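name	formula	pathway_group	ion_modes
hexose	C6H12O6	glycolysis	deprotonated
hexose_phosphate	C6H13O9P	glycolysis	deprotonated
hexose_disaccharide	C12H22O11	glycolysis	deprotonated,chloride
pyruvate	C3H4O3	glycolysis	deprotonated
phosphoenolpyruvate	C3H5O6P	glycolysis	deprotonated
dihydroxyacetone_phosphate	C3H7O6P	glycolysis	deprotonated
glycerol_3_phosphate	C3H9O6P	phospholipid	deprotonated
malate	C4H6O5	TCA	deprotonated
citrate	C6H8O7	TCA	deprotonated
succinate	C4H6O4	TCA	deprotonated
fumarate	C4H4O4	TCA	deprotonated
alpha_ketoglutarate	C5H6O5	TCA	deprotonated
oxaloacetate	C4H4O5	TCA	deprotonated
glutamate	C5H9NO4	amino_acid	deprotonated
aspartate	C4H7NO4	amino_acid	deprotonated
quinic_acid	C7H12O6	other	deprotonated
shikimate	C7H10O5	other	deprotonated
salicylate	C7H6O3	other	deprotonated
atp	C10H16N5O13P3	other	deprotonated,double_deprotonated
adp	C10H15N5O10P2	other	deprotonated
ascorbate	C6H8O6	redox	deprotonated
dehydroascorbate	C6H6O6	redox	deprotonated
glutathione	C10H17N3O6S	redox	deprotonated
glutathione_oxidized	C20H32N6O12S2	redox	deprotonated
hexose_phosphate+hexose	C6H13O9P+C6H12O6	glycolysis	cluster_deprotonated
hexose_disaccharide_dimer	C12H22O11+C12H22O11	glycolysis	cluster_deprotonated
PG(32:1)	C38H73O10P	phospholipid	deprotonated
PG(34:1)	C40H77O10P	phospholipid	deprotonated
PG(34:2)	C40H75O10P	phospholipid	deprotonated
PG(36:2)	C42H79O10P	phospholipid	deprotonated
PG(36:3)	C42H77O10P	phospholipid	deprotonated
PC(31:2)	C39H74NO8P	phospholipid	deprotonated
PE(34:2)	C39H74NO8P	phospholipid	deprotonated
PC(33:4)	C41H74NO8P	phospholipid	deprotonated
PS(33:0)	C39H76NO10P	phospholipid	deprotonated
PI(34:2)	C43H79O13P	phospholipid	deprotonated
PI(36:2)	C45H83O13P	phospholipid	deprotonated
MGDG(36:5)	C45H76O10	phospholipid	deprotonated
CL(70:4)	C79H146O17P2	CL	double_deprotonated
CL(70:5)	C79H144O17P2	CL	double_deprotonated
CL(74:5)	C83H152O17P2	CL	double_deprotonated
CL(74:6)	C83H150O17P2	CL	double_deprotonated
CL(74:7)	C83H148O17P2	CL	double_deprotonated
CL(74:8)	C83H146O17P2	CL	double_deprotonated
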