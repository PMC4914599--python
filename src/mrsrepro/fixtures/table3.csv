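region,metabolite,mean_crlb_percent,crlb_range_min,crlb_range_max,mean_concentration,intra_sd,intra_cv_percent,inter_sd,inter_cv_percent,provenance
aMCC,mI,6.7,5,11,4.4,0.36,8.8,0.63,14.3,transcribed printed per-cell summary
aMCC,Cre,4.2,4,5,5.3,0.25,4.7,0.47,8.8,transcribed printed per-cell summary
aMCC,Glu,6.9,6,8,10.2,0.48,4.7,0.70,6.9,transcribed printed per-cell summary
aMCC,tCho,4.5,3,6,1.8,0.11,5.8,0.16,8.7,transcribed printed per-cell summary
aMCC,tNAA,3.7,3,4,8.1,0.27,3.4,0.66,8.1,transcribed printed per-cell summary
aMCC,Glx,6.1,5,7,14.6,0.70,4.8,1.10,7.5,transcribed printed per-cell summary
pgACC,mI,6.5,5,8,4.9,0.41,8.2,0.58,11.8,transcribed printed per-cell summary
pgACC,Cre,4.2,3,5,5.7,0.32,5.8,0.41,7.3,transcribed printed per-cell summary
pgACC,Glu,6.6,5,8,11.2,0.70,6.2,1.06,9.5,transcribed printed per-cell summary
pgACC,tCho,4.9,4,6,2.0,0.17,8.7,0.18,8.9,transcribed printed per-cell summary
pgACC,tNAA,4.4,4,6,8.0,0.36,4.4,0.62,7.7,transcribed printed per-cell summary
pgACC,Glx,6.0,5,7,15.9,0.97,6.1,1.23,7.8,transcribed printed per-cell summary
pIL,mI,8.7,7,20,4.4,0.39,9.9,0.74,16.7,transcribed printed per-cell summary
pIL,Cre,4.6,4,5,5.9,0.27,4.5,0.35,5.9,transcribed printed per-cell summary
pIL,Glu,8.6,7,12,10.4,1.06,10.1,1.16,11.1,transcribed printed per-cell summary
pIL,tCho,5.7,4,7,1.8,0.12,6.6,0.18,10.1,transcribed printed per-cell summary
pIL,tNAA,4.6,4,6,8.2,0.35,4.2,0.49,6.0,transcribed printed per-cell summary
pIL,Glx,7.6,6,9,14.7,1.24,8.4,1.51,10.2,transcribed printed per-cell summary
pIR,mI,9.1,6,16,4.6,0.44,9.6,0.65,14.0,transcribed printed per-cell summary
pIR,Cre,5.0,4,6,5.9,0.48,7.9,0.57,9.7,transcribed printed per-cell summary
pIR,Glu,9.1,7,12,10.6,1.05,10.2,1.25,11.8,transcribed printed per-cell summary
pIR,tCho,6.6,5,10,1.7,0.12,7.0,0.17,10.0,transcribed printed per-cell summary
pIR,tNAA,4.6,4,7,8.3,0.47,5.7,0.58,6.9,transcribed printed per-cell summary
pIR,Glx,8.1,6,11,15.1,1.35,8.9,1.65,10.9,transcribed printed per-cell summary
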