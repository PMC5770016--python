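specimen_id,glg_label,mean_um,pred_1glg_um,pred_2glg_um,days,err_minus,err_plus
2012LDL3,a,1.47,1.32,2.64,327.10,17.37,19.44
2012LDL3,b,1.41,1.12,2.24,290.00,17.32,19.66
2012LDL8,a,1.79,1.92,3.84,391.84,30.54,36.18
2012LDL8,b,2.05,1.95,3.90,347.97,21.81,24.93
2012LDL8,c,1.87,1.94,3.88,378.27,22.31,25.29
2009LDL10,a,1.46,1.45,2.91,363.03,18.89,21.09
2009LDL10,b,1.50,1.57,3.14,381.36,24.27,27.81
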