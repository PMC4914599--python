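region,quantity,mean,sd,unit,provenance
aMCC,snr,16,1.79,ratio,transcribed printed quality-tissue summary
pgACC,snr,12.78,1.71,ratio,transcribed printed quality-tissue summary
pIL,snr,11.94,1.37,ratio,transcribed printed quality-tissue summary
pIR,snr,11.28,1.43,ratio,transcribed printed quality-tissue summary
aMCC,water_linewidth,0.0532,0.0004,ppm,transcribed printed quality-tissue summary (linewidths in ppm per the running text)
pgACC,water_linewidth,0.0711,0.010,ppm,transcribed printed quality-tissue summary (linewidths in ppm per the running text)
pIL,water_linewidth,0.0513,0.0025,ppm,transcribed printed quality-tissue summary (linewidths in ppm per the running text)
pIR,water_linewidth,0.0514,0.0020,ppm,transcribed printed quality-tissue summary (linewidths in ppm per the running text)
aMCC,voxel_volume,4.14,,ml,transcribed printed quality-tissue summary
pgACC,voxel_volume,3.46,,ml,transcribed printed quality-tissue summary
pIL,voxel_volume,3.04,,ml,transcribed printed quality-tissue summary
pIR,voxel_volume,3.04,,ml,transcribed printed quality-tissue summary
aMCC,gm_fraction,74.58,2.36,percent,transcribed printed quality-tissue summary
pgACC,gm_fraction,80.85,2.07,percent,transcribed printed quality-tissue summary
pIL,gm_fraction,77.62,2.89,percent,transcribed printed quality-tissue summary
pIR,gm_fraction,77.68,4.38,percent,transcribed printed quality-tissue summary
aMCC,wm_fraction,8.48,3.10,percent,transcribed printed quality-tissue summary
pgACC,wm_fraction,4.29,1.89,percent,transcribed printed quality-tissue summary
pIL,wm_fraction,8.24,2.01,percent,transcribed printed quality-tissue summary
pIR,wm_fraction,7.53,1.99,percent,transcribed printed quality-tissue summary
aMCC,csf_fraction,16.86,3.58,percent,transcribed printed quality-tissue summary
pgACC,csf_fraction,14.77,2.98,percent,transcribed printed quality-tissue summary
pIL,csf_fraction,14.04,2.75,percent,transcribed printed quality-tissue summary
pIR,csf_fraction,14.70,0.65,percent,transcribed printed quality-tissue summary
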