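name,low,high,scale
K_EG,100,1000,log10
K_CBHA,100,1000,log10
K_CBHD,10,100,log10
K_BGL,100,1000,log10
K_XYL,100,1000,log10
n_EG0,10,100,log10
n_CBH0,10,100,log10
n_BGL0,10,100,log10
n_XYL0,10,100,log10
X_cellulose,0,1,linear
X_hemicellulose,0,1,linear
r_cellulose,0.001,0.01,log10
r_hemicellulose,0.001,0.01,log10
L_adh,1,100,log10
omega_EG_glc,0,1,linear
omega_CBH_glc,0,1,linear
omega_BGL_glc,0,1,linear
omega_EG_cbs,0,1,linear
omega_CBH_cbs,0,1,linear
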