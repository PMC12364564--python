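family,species,svl_mm,spine_count,largest_spine_volume_mm3,highest_structural_curvature_deg,count_underestimated
Colubridae,Ahaetulla nasuta,628,489,0.02372,45.79,False
Colubridae,Nerodia fasciata,516,955,0.26906,97.69,False
Colubridae,Nerodia rhombifer,664,2698,1.04361,54.58,True
Colubridae,Nerodia sipedon,487,1292,0.24166,109.69,True
Colubridae,Opheodrys aestivus,,769,0.11474,73.68,False
Colubridae,Pantherophis alleghaniensis,1222,469,0.03729,26.56,False
Colubridae,Pantherophis guttatus,805,337,0.00629,36.7,False
Elapidae,Acanthophis rugosus,480,419,0.00794,24.55,False
Lamprophiidae,Mehelya crossi,1055,975,0.01896,76.01,False
Viperidae,Crotalus atrox,827,301,0.03822,16.89,False
Viperidae,Crotalus viridis,763,308,0.03822,28.89,False
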