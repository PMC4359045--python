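taxon,specimen,clade,mass_g,known_mass,humeral_length_mm,laminarity_index,li_ci,zp_mm3
Rhinolophus lepidus,pers. coll. H1-2,bat,6,False,24,0,,0.163
Macrotus californicus,UA 3767 H1-2,bat,12,False,28,0,,0.284
Myotis myotis,literature,bat,29,False,33,,,0.435
Phyllostomus discolor,UA 16197 H1-1,bat,34,False,35,0,,0.921
Noctilio leporinus,UA 15743 H1-2,bat,61,False,42,0,,2.426
Rousettus leschenaultii,pers. coll. H1-2,bat,108,False,54,0,,3.312
Pteropus vampyrus,pers. coll. H1-2,bat,1024,False,129,0,,30.586
Oceanodroma tethys,NMNH 614194,bird,23,False,28,,,0.627
Oceanites oceanicus,CMNH 7752,bird,29,False,22,,,0.790
Phalaenoptilus nuttallii,MWU 264 H1-1,bird,48,False,32,0.259,0.082,1.156
Bulweria bulwerii,NMNH 556263,bird,99,False,59,,,2.265
Nothura darwinii,UF 22260 H1-2,bird,274,False,43,0.316,0.055,4.762
Crypturellus boucardi,UF 44840 H1-1,bird,418,False,48,0.211,0.057,10.238
Crypturellus cinnamomeus,UA 8699 H2-1,bird,422,False,50,0.388,0.047,12.156
Columba livia,MWU 256 H1-2,bird,455,True,49,0.063,0.024,11.801
Nothoprocta cinerascens,UF 38951 H1-2,bird,480,True,59,0.462,0.048,12.921
Calonectris diomedea,OUVC 10438,bird,535,False,125,0.070,,28.887
Nothocercus nigrocapillus,UF 43432 H1-2,bird,605,True,60,0.115,0.037,11.896
Eudromia elegans,UF 22257 H1-1,bird,680,False,62,0.578,0.052,14.756
Tinamus major,UF 44828 H1-2,bird,960,False,73,0.316,0.044,34.868
Buteo jamaicensis,OUVC 10506,bird,1126,False,109,0.703,,50.879
Anhinga anhinga,OUVC 10432,bird,1235,False,126,0.233,,39.635
Phalacrocorax auritus,OUVC 10482,bird,1960,False,144,0.390,,39.449
Cathartes aura,OUVC 9648,bird,2006,False,160,0.376,,121.185
Pelecanus occidentalis,OUVC 10484,bird,3438,False,273,0.478,,163.645
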