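tip,angle_deg,force_gf,mean_area_mm2,sd_mm2,pca_printed_pct
flat,0,2,11.424,1.123,31
flat,0,4,10.861,1.188,29
flat,0,6,10.547,1.079,28
flat,0,10,14.041,1.245,38
flat,0,15,15.458,1.392,41
flat,0,20,15.358,1.624,41
flat,0,30,16.405,1.050,44
flat,0,40,19.097,1.294,51
flat,30,2,6.002,0.908,16
flat,30,4,7.406,0.594,20
flat,30,6,7.941,1.625,21
flat,30,10,9.607,1.284,26
flat,30,15,13.178,2.103,35
flat,30,20,14.644,2.609,39
flat,30,30,11.769,1.914,32
flat,30,40,14.759,1.196,40
flat,45,2,7.058,0.928,19
flat,45,4,7.027,0.608,19
flat,45,6,10.199,0.873,27
flat,45,10,10.463,0.883,28
flat,45,15,11.820,0.680,32
flat,45,20,12.842,1.438,34
flat,45,30,14.860,1.672,40
flat,45,40,19.533,1.361,52
flat,60,2,4.641,0.605,12
flat,60,4,7.247,1.228,19
flat,60,6,8.163,1.791,22
flat,60,10,10.094,1.996,27
flat,60,15,11.131,1.590,30
flat,60,20,11.431,1.699,31
flat,60,30,12.114,1.443,33
flat,60,40,13.515,0.895,36
flat,90,2,3.445,0.831,9
flat,90,4,4.392,0.514,12
flat,90,6,5.627,0.555,15
flat,90,10,6.879,0.874,18
flat,90,15,8.363,0.982,22
flat,90,20,7.405,1.126,20
flat,90,30,9.508,1.040,26
flat,90,40,12.589,0.812,34
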