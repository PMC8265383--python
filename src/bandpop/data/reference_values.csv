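quantity,value,tolerance
n_loci,148,0
n_individuals,136,0
n_populations,17,0
phipt,0.794,0.0005
pct_among,79,0.5
pct_within,21,0.5
ms_within,4.117,0.0005
sigma2_among,15.879,0.0005
phipt_subset,0.140,0.0005
pct_among_subset,14,0.5
pct_within_subset,86,0.5
ms_within_subset,0.418,0.0005
mean_pic,0.267,0.0005
he_R,0.1655,0.0005
pctP_R,45.27,0.005
he_J,0.0138,0.0005
pctP_J,3.38,0.005
mean_I,0.0758,0.0005
mean_He,0.0513,0.0005
mean_uHe,0.0547,0.0005
mean_Na,0.6586,0.0005
mean_Ne,1.0899,0.0005
pcoa_axis1_pct,22.22,0.12
pcoa_axis2_pct,12.26,0.07
pcoa_axis3_pct,10.56,0.06
pcoa_first3_pct,45.03,0.25
upgma_total_length,5.0639,0.0005
phipt_M_P,0.336,0.0005
phipt_I_N,0.917,0.0005
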