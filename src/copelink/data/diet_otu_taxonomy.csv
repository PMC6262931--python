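otu,phylum,taxon,closest_match,identity_pct
Cop1,Crustacea,Brachyura,Pirimela denticulata,99
Cop2,Crustacea,Brachyura,Polybius henslowii,100
Cop3,Crustacea,Brachyura,Goneplax rhomboides,100
Cop4,Crustacea,Anomura,Pisidia longicornis,100
Cop5,Crustacea,Euphausiacea,Nyctiphanes couchii,97
Cop6,Crustacea,Gebiidea,Jaxea nocturna,98
Cop7,Crustacea,Axiidea,Callianassa subterranea,99
Cop8,Crustacea,Axiidea,Callianassa sp.,93
Cop9,Crustacea,Axiidea,Callianassidae,90
Cop10,Crustacea,Gebiidea,Upogebiidae,81
Cop11,Crustacea,Caridea,Alpheus glaber,96
Cop12,Crustacea,Caridea,Alpheidae,78
Cop13,Crustacea,Copepoda,Metridia lucens,96
Cop14,Mollusca,Bivalvia,Limnoperna securis,98
Cop15,Mollusca,Bivalvia,Mytilidae,87
Cop16,Chordata,Teleostei,Gobiinae,92
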