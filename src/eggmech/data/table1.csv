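species,group,length_mm,width_mm,thickness_mm,egg_mass_g,fbm_max_kg,fbm_min_kg,mbm_max_kg,mbm_min_kg,dimorphism,extinct,esr_percent_printed
Struthio camelus,ostrich,158,131,1.92,1600,85,63,130,80,SSD,False,1.79
Rhea americana,rhea,128,86,0.9,525,40,20,,,none,False,1.75
Rhea pennata,rhea,126,92,0.86,584,25,15,,,none,False,2.92
Dromaius novaehollandiae,emu,136,89,0.94,610,45,35,30,20,RSSD,False,1.88
Casuarius casuarius,cassowary,135,92,0.97,644,50,35,30,25,RSSD,False,1.84
Casuarius unappendiculatus,cassowary,136,90,0.97,604,64.35,52.65,40.7,33.3,RSSD,False,1.26
Apteryx owenii,kiwi,110,70,0.4,295,1.9,1,1.3,0.9,RSSD,False,23.17
Apteryx haastii,kiwi,123,77,0.53,400,3.3,1.5,2.6,1.2,RSSD,False,18.59
Apteryx mantelli,kiwi,125,78,0.5,417,3.27,2.09,2.59,1.82,RSSD,False,17.06
Aepyornis maximus,elephant bird,303,224,3.7,9120,541,334,,,none,True,2.08
Megalapteryx didinus,moa,160,108,1.17,1023,80,28,,,none,True,1.89
Dinornis novaezealandiae,moa,190,150,1.375,2343,160,91,69,34,RSSD,True,2.65
Dinornis robustus,moa,240,178,1.23,4167,275,102,113,61,RSSD,True,3.03
Pachyornis elephantopus,moa,221,150,1.79,2725,106,49,,,none,True,3.52
Anomalopteryx didiformis,moa,165,120,1.39,1302,64,26,,,none,True,2.89
Euryapteryx curtus curtus,moa,121,97,0.9,624,30,20,20,15,RSSD,True,2.94
Euryapteryx curtus gravis,moa,205,158,1.5,2804,105,67,80,55,RSSD,True,3.65
Emeus crassus,moa,179,134,1,1761,80,52,50,36,RSSD,True,3.23
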