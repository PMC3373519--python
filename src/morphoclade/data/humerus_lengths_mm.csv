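taxon,specimen,subfamily,humerus_length_mm,estimated
Brachylophosaurus canadensis,MOR 794,Saurolophinae,595,0
Edmontosaurus regalis,CMN 8399,Saurolophinae,623,0
Edmontosaurus regalis,ROM 801,Saurolophinae,674,0
Edmontosaurus annectens,SM R4036,Saurolophinae,520,0
Edmontosaurus annectens,YPM 2182,Saurolophinae,560,0
Gryposaurus notabilis,ROM 764,Saurolophinae,600,0
Gryposaurus notabilis,MSNM V345,Saurolophinae,705,0
Prosaurolophus maximus,ROM 787,Saurolophinae,532,0
Saurolophus osborni,AMNH 5220,Saurolophinae,600,0
Shantungosaurus giganteus,GMV 1780,Saurolophinae,915,0
Magnapaulia laticaudus,LACM 17712,Lambeosaurinae,803,1
Magnapaulia laticaudus,LACM 17716,Lambeosaurinae,650,0
Magnapaulia laticaudus,LACM 17715,Lambeosaurinae,600,0
cf Parasaurolophus,AMNH 5893,Lambeosaurinae,600,0
Tsintaosaurus spinorhinus,IVPP V725,Lambeosaurinae,568,0
Parasaurolophus cyrtocristatus,FMNH P27393,Lambeosaurinae,565,0
Olorotitan arharensis,AEHM 2/845,Lambeosaurinae,540,0
Lambeosaurinae indeterminate,FMNH UC1479,Lambeosaurinae,502,0
Parasaurolophus walkeri,ROM 768,Lambeosaurinae,520,0
Hypacrosaurus altispinus,CMN 8501,Lambeosaurinae,530,0
Corythosaurus casuarius,ROM 845,Lambeosaurinae,430,0
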