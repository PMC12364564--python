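species,spine_id,tip_angle_deg,tip_roc_norm,puncture_range_deg,lowest_force_N,average_force_N,broken
Opheodrys aestivus,OPAE_2,26.441,0.080,50,3.48,4.32,False
Opheodrys aestivus,OPAE_3,83.735,0.193,0,,,False
Crotalus viridis,CRVI_1,68.605,0.082,30,18.38,32.45,False
Nerodia rhombifer,NERH_1,37.512,0.064,60,10.31,17.87,False
Nerodia rhombifer,NERH_2,42.525,0.078,60,12.02,25.53,False
Nerodia rhombifer,NERH_3,56.396,0.082,60,26.16,45.85,False
Nerodia rhombifer,NERH_4,57.850,0.082,60,29.46,42.38,False
Nerodia rhombifer,NERH_5,12.795,0.025,20,5.50,6.90,True
Mehelya crossi,MECR_1,63.031,0.064,30,40.83,46.51,False
Crotalus atrox,CRAT_1,57.938,0.111,50,36.14,43.42,False
Nerodia sipedon,NESI_5,60.870,0.069,50,5.77,6.69,False
Acanthophis rugosus,ACRU_1,59.583,0.040,60,33.16,47.66,False
Pantherophis alleghaniensis,PAAL_3,43.338,0.089,40,28.37,32.50,False
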