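marker,major_allele_frequency,genotype_no,sample_size,n_obs,allele_no,gene_diversity,heterozygosity,pic
Hpms1-214,0.35,8,85,85,7,0.72,0.01,0.67
Gpms104,0.49,7,85,85,8,0.57,0.93,0.47
Epms331,0.28,14,85,85,11,0.82,0.06,0.79
Epms755,0.66,3,85,85,2,0.45,0.02,0.35
Epms397,0.21,13,85,85,9,0.84,0.05,0.82
Es350,0.99,2,85,85,2,0.01,0.01,0.01
Gpms6,0.97,3,85,85,3,0.06,0.06,0.06
InDel-3-5,0.33,10,85,85,11,0.80,0.01,0.78
Hpms1-111,0.56,10,85,85,7,0.61,0.09,0.57
Epms386,0.58,7,85,85,7,0.59,0.01,0.55
HpmsAT2-14,0.95,4,85,85,3,0.09,0.02,0.09
Epms391,0.83,4,85,85,3,0.29,0.01,0.25
Epms310,0.50,10,85,85,9,0.69,0.01,0.66
HpmsE095,0.93,4,85,85,4,0.13,0.00,0.13
Gpms101,0.59,6,85,85,5,0.50,0.07,0.39
Epms725,0.98,3,85,85,3,0.03,0.01,0.03
HpmsCaSIG19,0.32,15,85,85,8,0.79,0.12,0.76
Epms419,0.66,9,85,85,6,0.52,0.05,0.48
HpmsE008,0.45,7,85,85,4,0.69,0.04,0.64
HpmsE088,0.59,9,85,85,9,0.60,0.00,0.57
EPMS680,0.85,4,85,85,4,0.27,0.00,0.26
Epms342,0.66,23,85,85,19,0.55,0.15,0.54
GPMS29,0.46,9,85,85,8,0.72,0.04,0.68
Hpms2-24,0.71,7,85,85,6,0.46,0.02,0.42
HpmsE013,0.71,6,85,85,6,0.47,0.00,0.43
Gpms169,0.81,7,85,85,7,0.33,0.01,0.32
HpmsE128,0.68,5,85,85,4,0.45,0.04,0.37
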