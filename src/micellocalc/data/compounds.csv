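name,smiles,tags
Ethylbenzene,CCc1ccccc1,benzene derivative
Propylbenzene,CCCc1ccccc1,benzene derivative
Butylbenzene,CCCCc1ccccc1,benzene derivative
1-Phenylethanone,CC(=O)c1ccccc1,aryl ketone
1-Phenylpropan-1-one,CCC(=O)c1ccccc1,aryl ketone
1-Phenylbutan-1-one,CCCC(=O)c1ccccc1,aryl ketone
1-Phenylpentan-1-one,CCCCC(=O)c1ccccc1,aryl ketone
1-Phenylheptan-1-one,CCCCCCC(=O)c1ccccc1,aryl ketone
Furan,c1ccoc1,heterocycle
2-Nitroaniline,Nc1ccccc1[N+](=O)[O-],nitroaniline
"2,3-Benzofuran",c1ccc2occc2c1,heterocycle
Diphenylmethanone,O=C(c1ccccc1)c1ccccc1,aryl ketone
Benzamide,NC(=O)c1ccccc1,amide
4-Chloroaniline,Nc1ccc(Cl)cc1,aniline
"2,3-Dimethylphenol",Cc1cccc(O)c1C,phenol
Naphtalen-2-ol,Oc1ccc2ccccc2c1,phenol
4-Aminobenzamide,NC(=O)c1ccc(N)cc1,amide
3-Methylphenol,Cc1cccc(O)c1,phenol
"2,4-Dimethylphenol",Cc1ccc(O)c(C)c1,phenol
Naphthalene,c1ccc2ccccc2c1,polycyclic aromatic
Pyrimidine,c1cncnc1,azine heterocycle
Benzaldehyde,O=Cc1ccccc1,aldehyde
3-Chloroaniline,Nc1cccc(Cl)c1,aniline
Pyrrole,c1cc[nH]c1,azole heterocycle
3-Nitroaniline,Nc1cccc([N+](=O)[O-])c1,nitroaniline
4-Chlorophenol,Oc1ccc(Cl)cc1,phenol
Phenol,Oc1ccccc1,phenol
Methylbenzoate,COC(=O)c1ccccc1,ester
Bromobenzene,Brc1ccccc1,halobenzene
"1,4-Xylene",Cc1ccc(C)cc1,benzene derivative
"Benzene-1,3-diol",Oc1cccc(O)c1,phenol
2-Methylaniline,Cc1ccccc1N,aniline
Aniline,Nc1ccccc1,aniline
Nitrobenzene,O=[N+]([O-])c1ccccc1,nitrobenzene
Chlorobenzene,Clc1ccccc1,halobenzene
N-4-chlorophenylacetamide,CC(=O)Nc1ccc(Cl)cc1,anilide
N-Phenylacetamide,CC(=O)Nc1ccccc1,anilide
4-Nitroaniline,Nc1ccc([N+](=O)[O-])cc1,nitroaniline
Anisole,COc1ccccc1,ether
Benzonitrile,N#Cc1ccccc1,nitrile
1-Ethyl-4-nitrobenzene,CCc1ccc([N+](=O)[O-])cc1,nitrobenzene
Benzyl benzoate,O=C(OCc1ccccc1)c1ccccc1,ester
Caffeine,Cn1cnc2c1c(=O)n(C)c(=O)n2C,xanthine alkaloid
Corticosterone,CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2C(=O)CO,hormone
Cortisone,CC12CCC(=O)C=C1CCC1C2C(=O)CC2(C)C1CCC2(O)C(=O)CO,hormone
beta-Estradiol,CC12CCC3c4ccc(O)cc4CCC3C1CCC2O,hormone
Estriol,CC12CCC3c4ccc(O)cc4CCC3C1CC(O)C2O,hormone
Cortisol,CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO,hormone
Hydroquinone,Oc1ccc(O)cc1,phenol
Quinoline,c1ccc2ncccc2c1,azine heterocycle
Atrazine,CCNc1nc(Cl)nc(NC(C)C)n1,triazine pesticide
Diuron,CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1,urea herbicide
Isoproturon,CC(C)c1ccc(NC(=O)N(C)C)cc1,urea herbicide
Linuron,CON(C)C(=O)Nc1ccc(Cl)c(Cl)c1,urea herbicide
Metobromuron,CON(C)C(=O)Nc1ccc(Br)cc1,urea herbicide
Monuron,CN(C)C(=O)Nc1ccc(Cl)cc1,urea herbicide
Metoxuron,COc1ccc(NC(=O)N(C)C)cc1Cl,urea herbicide
Phenylurea,NC(=O)Nc1ccccc1,urea herbicide
Propazine,CC(C)Nc1nc(Cl)nc(NC(C)C)n1,triazine pesticide
Fluometuron,CN(C)C(=O)Nc1cccc(C(F)(F)F)c1,urea herbicide
N-N-Diethyl-4-nitroaniline,CCN(CC)c1ccc([N+](=O)[O-])cc1,nitroaniline
1-Methoxy-4-nitrobenzene,COc1ccc([N+](=O)[O-])cc1,nitrobenzene
1-Methoxy-2-nitrobenzene,COc1ccccc1[N+](=O)[O-],nitrobenzene
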