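taxon,areas
Aralosaurus_tuberiferus,AS
Tsintaosaurus_spinorhinus,AS
Pararhabdodon_isonensis,E
Jaxartosaurus_aralensis,AS
Amurosaurus_riabinini,AS
Sahaliyania_elunchunorum,AS
Charonosaurus_jiayinensis,AS
Parasaurolophus_walkeri,NNA
Parasaurolophus_tubicen,SNA
Parasaurolophus_cyrtocristatus,SNA
Corythosaurus_casuarius,NNA
Corythosaurus_intermedius,NNA
Lambeosaurus_lambei,NNA
Lambeosaurus_magnicristatus,NNA
Hypacrosaurus_stebingeri,NNA
Hypacrosaurus_altispinus,NNA
Olorotitan_arharensis,AS
Magnapaulia_laticaudus,SNA
Velafrons_coahuilensis,SNA
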