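marker,major_allele_frequency,genotype_no,sample_size,n_obs,allele_no,gene_diversity,heterozygosity,pic
Hpms1-214,0.71,19,94,94,15,0.49,0.13,0.47
Gpms104,0.51,5,94,94,6,0.53,0.94,0.43
Epms331,0.22,31,94,94,20,0.88,0.22,0.87
Epms755,0.63,8,94,94,6,0.52,0.14,0.44
Epms397,0.24,24,94,94,14,0.86,0.21,0.84
Es350,0.41,10,94,94,6,0.72,0.09,0.67
Gpms6,0.72,9,94,94,10,0.45,0.45,0.42
InDel-3-5,0.53,14,94,94,10,0.68,0.13,0.66
Hpms1-111,0.51,13,94,94,6,0.67,0.24,0.64
Epms386,0.42,22,94,94,15,0.75,0.18,0.72
HpmsAT2-14,0.87,9,94,94,7,0.24,0.05,0.24
Epms391,0.91,3,94,94,2,0.16,0.02,0.14
Epms310,0.27,26,94,94,14,0.84,0.20,0.82
HpmsE095,0.89,12,94,94,10,0.21,0.09,0.21
Gpms101,0.75,5,94,94,4,0.38,0.07,0.33
Epms725,0.85,8,94,94,6,0.28,0.07,0.26
HpmsCaSIG19,0.58,12,94,94,7,0.61,0.14,0.58
Epms419,0.60,10,94,94,7,0.59,0.11,0.56
HpmsE008,0.44,13,94,94,8,0.72,0.13,0.68
HpmsE088,0.76,10,94,94,8,0.41,0.05,0.38
EPMS680,0.78,10,94,94,9,0.38,0.03,0.37
Epms342,0.27,27,94,94,19,0.86,0.17,0.85
GPMS29,0.31,18,94,94,8,0.79,0.17,0.76
Hpms2-24,0.28,15,94,94,9,0.81,0.16,0.79
HpmsE013,0.53,14,94,94,11,0.66,0.07,0.63
Gpms169,0.72,13,94,94,10,0.46,0.10,0.43
HpmsE128,0.82,5,94,94,4,0.30,0.01,0.27
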