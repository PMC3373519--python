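(Aralosaurus_tuberiferus,((Tsintaosaurus_spinorhinus,Pararhabdodon_isonensis),(Jaxartosaurus_aralensis,((Amurosaurus_riabinini,Sahaliyania_elunchunorum),((Charonosaurus_jiayinensis,(Parasaurolophus_walkeri,(Parasaurolophus_tubicen,Parasaurolophus_cyrtocristatus))),((((Corythosaurus_casuarius,Corythosaurus_intermedius),(Lambeosaurus_lambei,Lambeosaurus_magnicristatus)),(Hypacrosaurus_stebingeri,(Hypacrosaurus_altispinus,Olorotitan_arharensis))),(Magnapaulia_laticaudus,Velafrons_coahuilensis)))))));
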