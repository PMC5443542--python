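common_name,scientific_name,cosewic_status,range_weight,in_original_ohi,salmon_reference
Lobster,Homarus americanus,Not Assessed,1.0,False,False
Leather star,Dermasterias imbricata,Not Assessed,1.0,False,False
Atlantic Cod,Gadus morhua,Not Assessed,1.0,False,False
Chum Salmon,Oncorhynchus keta,Not Assessed,1.0,False,True
Coho Salmon,Oncorhynchus kisutch,Not Assessed,1.0,False,True
Pink Salmon,Oncorhynchus gorbuscha,Not Assessed,1.0,False,True
Rainbow Trout,Oncorhynchus mykiss,Not Assessed,1.0,False,False
Sockeye Salmon,Oncorhynchus nerka,Not Assessed,1.0,False,False
Chinook Salmon,Oncorhynchus tshawytscha,Not Assessed,1.0,False,True
Atlantic Salmon,Salmo salar,Not Assessed,1.0,False,False
Arctic Char,Salvelinus alpinus,Not Assessed,1.0,False,False
Orca,Orcinus orca,Not Assessed,1.0,False,False
Humpback,Megaptera novaeangliae,Not Assessed,1.0,True,False
Bowhead,Balaena mysticetus,Not Assessed,1.0,True,False
Blue whale,Balaenoptera musculus,Not Assessed,1.0,True,False
Beluga,Delphinapterus leucas,Not Assessed,1.0,False,False
Polar Bear,Ursus maritimus,Not Assessed,1.0,True,False
Common Loon,Gavia immer,Not Assessed,1.0,False,False
Bald Eagle,Haliaeetus leucocephalus,Not Assessed,1.0,False,False
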