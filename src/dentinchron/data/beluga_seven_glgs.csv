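specimen_id,glg_label,sex,tooth_position,whale_length_cm,thickness_um,preparation,mean_um,three_se_um,sum_um,n
2012LDL3,a,F,6,362,482.00,demineralized,1.47,0.08,178.30,121
2012LDL3,b,F,6,362,408.82,demineralized,1.41,0.09,170.58,121
2012LDL8,a,M,2,385,700.30,demineralized,1.79,0.15,201.95,113
2012LDL8,b,M,2,385,711.62,demineralized,2.05,0.14,214.73,105
2012LDL8,c,M,2,385,707.62,demineralized,1.87,0.12,411.55,220
2009LDL10,a,M,3,334,531.00,demineralized,1.46,0.08,203.32,139
2009LDL10,b,M,3,334,573.63,demineralized,1.50,0.10,154.93,103
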