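micelle,solvent,filter,slope,intercept,r2,mae
LPFOS,propan-1-ol,all,0.46,0.77,0.52,0.87
LPFOS,propan-2-ol,all,0.49,0.61,0.53,0.92
LPFOS,methanol,all,0.41,0.90,0.43,0.86
SC,propan-1-ol,all,0.47,0.55,0.67,0.92
SC,propan-2-ol,all,0.46,0.51,0.64,1.08
SC,methanol,all,0.41,0.68,0.58,0.89
HTAB,propan-1-ol,all,0.23,1.80,0.13,0.74
HTAB,propan-2-ol,all,0.22,1.83,0.10,0.72
HTAB,methanol,all,0.24,1.78,0.13,0.72
HTAB,propan-1-ol,no-nset,0.56,1.24,0.66,0.45
HTAB,propan-2-ol,no-nset,0.54,1.24,0.62,0.43
HTAB,methanol,no-nset,0.56,1.26,0.63,0.46
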