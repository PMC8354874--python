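tip,angle_deg,force_gf,mean_area_mm2,sd_mm2,pca_printed_pct
round,0,2,6.365,0.508,25
round,0,4,8.730,0.840,34
round,0,6,9.039,1.040,35
round,0,10,10.325,1.159,40
round,0,15,11.779,1.292,46
round,0,20,12.343,1.042,48
round,0,30,13.661,0.852,53
round,0,40,15.578,1.274,61
round,30,2,6.055,1.075,24
round,30,4,6.999,0.825,27
round,30,6,9.982,0.768,39
round,30,10,12.579,1.107,49
round,30,15,14.417,2.141,56
round,30,20,13.697,1.857,53
round,30,30,17.693,1.394,65
round,30,40,16.788,0.581,65
round,45,2,3.592,0.493,14
round,45,4,4.906,0.421,19
round,45,6,5.547,0.629,22
round,45,10,6.815,0.898,27
round,45,15,8.123,0.652,32
round,45,20,9.704,0.841,38
round,45,30,12.730,1.583,50
round,45,40,13.725,1.954,53
round,60,2,3.699,0.724,14
round,60,4,5.869,0.719,23
round,60,6,6.782,0.821,26
round,60,10,8.222,0.625,32
round,60,15,9.354,0.811,36
round,60,20,10.275,0.868,40
round,60,30,10.464,1.740,41
round,60,40,14.310,2.286,56
round,90,2,3.829,0.294,15
round,90,4,6.309,0.320,25
round,90,6,7.797,1.134,30
round,90,10,7.990,0.553,31
round,90,15,8.535,0.751,33
round,90,20,9.340,0.638,36
round,90,30,10.357,1.039,40
round,90,40,11.914,0.909,46
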