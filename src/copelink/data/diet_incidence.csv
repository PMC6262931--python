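copepod,species,condition,size_class,Cop1,Cop2,Cop3,Cop4,Cop5,Cop6,Cop7,Cop8,Cop9,Cop10,Cop11,Cop12,Cop13,Cop14,Cop15,Cop16
C1,"Diaixis pygmaea",downwelling,s,0,0,0,3,0,0,0,0,0,0,0,0,1,0,0,0
C2,"Clausocalanus sp.",downwelling,s,3,0,0,0,0,1,0,0,0,0,1,0,0,0,0,0
C3,"Temora longicornis",downwelling,s,2,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0
C4,"Acartia clausii",downwelling,s,4,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
C5,"Isias clavipes",downwelling,s,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,4
C6,"Centropages chierchiae",downwelling,s,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
C7,"Paraeuchaeta hebes",downwelling,l,4,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
C8,"Oithona sp.",upwelling,s,4,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C9,"Corycaeus sp.",upwelling,s,0,0,0,0,0,0,0,0,0,0,0,4,0,0,0,0
C10,"Paracalanus parvus",upwelling,s,3,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C11,"Pseudocalanus elongatus",upwelling,s,4,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C12,"Ctenocalanus vanus",upwelling,s,1,0,0,0,0,0,1,1,1,0,0,0,0,0,0,0
C13,"Aetideus armatus",upwelling,s,2,1,2,0,0,0,0,0,0,0,0,0,0,0,0,0
C14,"Centropages typicus",upwelling,s,1,0,0,0,0,0,0,0,0,0,0,0,0,2,1,0
C15,"Pleuromamma gracilis",upwelling,s,5,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
C16,"Calanoides carinatus",upwelling,l,2,0,0,0,0,2,0,0,0,1,0,0,0,0,0,0
C17,"Calanus helgolandicus",upwelling,l,2,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0
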