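parameter,axis,mean,sd,range_min,range_max,unit,provenance
translation,x,0.31,0.23,0.07,1.28,mm,transcribed printed movement summary
translation,y,0.43,0.24,0.08,1.51,mm,transcribed printed movement summary
translation,z,0.77,0.37,0.28,1.43,mm,transcribed printed movement summary
rotation,pitch,0.44,0.48,0.08,2.51,deg,transcribed printed movement summary
rotation,roll,0.30,0.19,0.04,0.79,deg,transcribed printed movement summary
rotation,yaw,0.55,0.40,0.10,1.78,deg,transcribed printed movement summary
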