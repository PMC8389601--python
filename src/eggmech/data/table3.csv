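species,common_name,length_mm,width_mm,thickness_mm,egg_mass_g,body_mass_g,C_printed,FS_printed
Diomedea exulans,Wandering Albatross,129.5,79.7,0.58,455.0,8190,3185,2.16
Phoebastria nigripes,Black-footed Albatross,108.2,69.2,0.50,286.0,3195,6328,4.81
Phoebetria palpebrata,Light-mantled Albatross,104.0,64.5,0.48,243.0,3150,5428,3.95
Macronectes giganteus,Southern Giant Petrel,104.4,65.9,0.58,237.0,4395,10865,5.61
Aptenodytes patagonicus,King Penguin,104.5,75.8,0.80,306.0,11751,13741,4.00
Cygnus columbianus,Tundra Swan,106.9,68.2,0.76,280.0,6750,12655,2.41
Pinguinus impennis,Great Auk,124.0,75.8,0.74,372.0,5000,8299,7.56
Rhea americana,Greater Rhea,128.0,86.0,0.90,525.0,23000,9637,2.80
Casuarius casuarius,Southern Cassowary,135.0,92.1,0.97,644.0,44000,9108,2.12
Dromaius novaehollandiae,Emu,136.0,89.0,0.94,610.0,34200,8043,2.02
Apteryx australis,Southern Brown Kiwi,125.8,78.5,0.50,434.0,2330,3924,2.79
Macrocephalon maleo,Maleo,105.6,61.7,0.38,222.0,1564,3488,3.20
Gymnogyps californianus,California Condor,110.2,66.7,0.92,280.0,8450,17911,6.08
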