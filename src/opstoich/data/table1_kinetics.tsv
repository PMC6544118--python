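enzyme_gene	k_cat	K_M	k_cat_organism	K_M_organism	homology_pct
ArgB	4.9	1.3	S. cerevisiae	E. coli	56
ArgC	14	0.4	E. coli	E. coli
ArgH	4.9	0.4	Anas platyrhynchos	Anas platyrhynchos	75
BioB	0.0039	0.002	E. coli	E. coli
BioF	0.05825	0.025	E. coli	E. coli
BioC	98.334	0.00108	Bacillus cereus	Bacillus cereus	62
GuaB	13	0.061	E. coli	E. coli
GuaA	23	0.053	E. coli	E. coli
AceB		0.022	E. coli	E. coli
AceA		0.063	E. coli	E. coli
BetA		1.5	E. coli	E. coli
BetB		1.8	E. coli	E. coli
UxuA		4.79	E. coli	E. coli
UxuB		1	E. coli	E. coli
DadA		30	E. coli	E. coli
DadX		3.03	E. coli	E. coli
ProB		1.2	E. coli	Pseudomonas aeruginosa	74
ProA		300	E. coli	E. coli
OtsA		1	E. coli	Thermoplasma acidophilum	65
OtsB		0.61	E. coli	E. coli
CysC		0.0005	E. coli	E. coli
CysD + CysN		0.0045	E. coli	Thiobacillus denitrificans	67
PurD		0.03	E. coli	E. coli
PurH		0.082	E. coli	Methanocaldococcus jannaschii	50
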