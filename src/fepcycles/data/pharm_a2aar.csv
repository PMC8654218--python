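ligand,variant,emax_percent,emax_sem,ec50_nM,profile
NECA,wt,100,0,,full_agonist
ADO,wt,45,0,,partial_agonist
Cyp-Ade,wt,0,0,,neutral_antagonist
CGS21680,wt,100,0,,full_agonist
LUF5833,wt,55,15,,partial_agonist
LUF5834,wt,55,15,,partial_agonist
LUF5835,wt,80,10,,partial_agonist
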