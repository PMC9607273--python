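id,name,smiles,rate_q,rate_r,is_test_q,is_test_r
c01,Phenyl acetate,CC(=O)Oc1ccccc1,100,100,0,0
c02,Paraoxon,CCOP(=O)(OCC)Oc1ccc(cc1)[N+](=O)[O-],0.13,0.99,0,0
c03,2-Coumaranone,O=C1Cc2ccccc2O1,18.3,13.5,0,0
c04,Dihydrocoumarin,O=C1CCc2ccccc2O1,14.3,17.0,1,1
c05,Homogentisic acid lactone,O=C1Cc2cc(O)ccc2O1,44.0,49.7,0,0
c06,gamma-Butyrolactone,O=C1CCCO1,2.46,9.05,1,0
c07,alpha-Bromo-gamma-butyrolactone,O=C1OCCC1Br,47.2,40.8,0,0
c08,S-alpha-Hydroxy-gamma-butyrolactone,O[C@H]1CCOC1=O,8.14,19.6,0,0
c09,S-beta-Hydroxy-gamma-butyrolactone,O=C1C[C@H](O)CO1,0.60,0.76,1,0
c10,gamma-Valerolactone,CC1CCC(=O)O1,7.28,6.97,1,0
c11,R-Dihydro-5-(hydroxymethyl)-2(3H)-furanone,OC[C@H]1CCC(=O)O1,1.23,3.29,0,0
c12,gamma-Decanolactone,CCCCCCC1CCC(=O)O1,12.4,19.0,0,0
c13,Undecano-gamma-lactone,CCCCCCCC1CCC(=O)O1,11.8,12.7,0,0
c14,alpha-Angelicolactone,CC1=CCC(=O)O1,19.9,14.8,0,0
c15,beta-Butyrolactone,CC1CC(=O)O1,3.83,7.53,0,0
c16,delta-Valerolactone,O=C1CCCCO1,75.4,71.0,0,0
c17,delta-Decanolactone,CCCCCC1CCCC(=O)O1,23.8,28.2,0,0
c18,Undecanoic-delta-lactone,CCCCCCC1CCCC(=O)O1,27.5,32.8,1,1
c19,delta-Dodecanolactone,CCCCCCCC1CCCC(=O)O1,9.65,12.8,0,0
c20,epsilon-Caprolactone,O=C1CCCCCO1,14.8,25.7,0,0
c21,Oxabicyclooctenone,O=C1CC2C=CCC2O1,1.67,2.92,0,0
c22,gamma-Thiobutyrolactone,O=C1CCCS1,0.04,0.11,0,0
c23,Homocysteine thiolactone,NC1CCSC1=O,0.004,0.009,0,0
c24,Propylene carbonate,CC1COC(=O)O1,5.02,8.80,1,0
c25,"4-(1-Propenyloxymethyl)-1,3-dioxolan-2-one",CC=COCC1COC(=O)O1,2.23,2.52,0,0
c26,"4-[(5-Methyl-2-oxo-1,3-dioxol-4-yl)methylthio]benzenesulfonate",CC1=C(CSc2ccc(S(=O)(=O)O)cc2)OC(=O)O1,1.46,9.65,0,1
c27,Sarin,CC(C)OP(C)(=O)F,0.14,0.02,0,0
c28,Soman,CC(C(C)(C)C)OP(C)(=O)F,0.85,0.55,0,1
c29,Diazoxon,CCOP(=O)(OCC)Oc1cc(C)nc(n1)C(C)C,4.88,4.45,0,1
c30,Chlorpyrifos oxon,CCOP(=O)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,2.97,5.40,0,0
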