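compound,SC,HTAB,LPFOS
Ethylbenzene,2.50,3.00,2.06
Propylbenzene,2.94,3.42,2.39
Butylbenzene,3.26,3.71,2.71
1-Phenylethanone,1.33,2.03,2.19
1-Phenylpropan-1-one,1.65,2.42,2.44
1-Phenylbutan-1-one,2.01,2.80,2.72
1-Phenylpentan-1-one,2.41,3.24,3.01
1-Phenylheptan-1-one,3.15,-,3.68
Furan,0.77,1.48,1.19
2-Nitroaniline,1.59,2.67,1.80
"2,3-Benzofuran",2.12,2.82,1.82
Diphenylmethanone,2.48,3.28,3.01
Benzamide,1.06,1.72,1.50
4-Chloroaniline,1.69,2.69,1.44
"2,3-Dimethylphenol",1.90,3.15,1.66
Naphtalen-2-ol,2.31,-,1.73
4-Aminobenzamide,0.98,1.11,1.76
3-Methylphenol,1.53,2.78,1.43
"2,4-Dimethylphenol",1.93,3.17,1.02
Naphthalene,2.67,3.47,2.09
Pyrimidine,0.56,-,1.27
Benzaldehyde,1.20,1.91,1.91
3-Chloroaniline,1.63,2.72,1.41
Pyrrole,0.68,1.65,0.72
3-Nitroaniline,1.38,2.42,1.53
4-Chlorophenol,2.00,3.24,1.30
Phenol,1.21,2.35,1.08
Methylbenzoate,1.71,2.39,2.36
Bromobenzene,2.37,2.95,1.80
"1,4-Xylene",2.51,3.04,2.10
"Benzene-1,3-diol",1.21,2.48,0.75
2-Methylaniline,1.17,2.15,1.59
Aniline,0.92,1.83,1.34
Nitrobenzene,1.47,2.21,1.94
Chlorobenzene,2.21,2.77,1.77
N-4-chlorophenylacetamide,2.03,2.80,1.84
N-Phenylacetamide,1.25,1.98,1.58
4-Nitroaniline,1.52,2.50,1.45
Anisole,1.66,2.31,1.83
Benzonitrile,1.21,1.96,1.95
1-Ethyl-4-nitrobenzene,2.19,3.02,2.68
Benzyl benzoate,2.99,-,3.18
Caffeine,1.11,1.32,1.85
Corticosterone,1.94,3.69,3.64
Cortisone,1.72,3.16,3.37
beta-Estradiol,2.77,-,2.84
Estriol,2.32,3.52,2.01
Cortisol,1.83,3.39,2.89
Hydroquinone,1.09,1.94,0.19
Quinoline,1.65,2.36,2.68
Atrazine,1.86,1.90,2.71
Diuron,2.46,2.19,2.34
Isoproturon,2.19,1.95,2.61
Linuron,2.59,2.24,2.50
Metobromuron,2.16,2.03,2.22
Monuron,1.81,1.73,2.03
Metoxuron,1.69,1.46,2.34
Phenylurea,1.20,1.20,1.38
Propazine,2.02,2.08,3.03
Fluometuron,2.01,1.92,2.57
N-N-Diethyl-4-nitroaniline,2.44,3.56,3.36
1-Methoxy-4-nitrobenzene,1.69,2.58,2.20
1-Methoxy-2-nitrobenzene,1.55,2.37,2.26
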