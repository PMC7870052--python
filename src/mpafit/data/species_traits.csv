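family,species,trophic_group,pelagic,present_at_control
Myliobatidae,Myliobatis aquila,MACRO,false,true
Clupeidae,Sarda sarda,PISC,true,false
Engraulidae,Engraulis encrasicolus,PLAN,true,true
Muraenidae,Muraena helena,PISC,false,true
Belonidae,Belone belone,PISC,true,false
Phycidae,Phycis phycis,PISC,false,true
Serranidae,Anthias anthias,PLAN,true,true
Serranidae,Epinephelus costae,PISC,false,true
Serranidae,Epinephelus marginatus,PISC,false,true
Serranidae,Epinephelus caninus,PISC,false,false
Serranidae,Mycteroperca rubra,PISC,false,true
Serranidae,Serranus atricauda,MACRO,false,true
Serranidae,Serranus cabrilla,MACRO,false,true
Serranidae,Serranus scriba,MACRO,false,true
Moronidae,Dicentrarchus labrax,PISC,false,true
Apogonidae,Apogon imberbis,MICRO,false,true
Carangidae,Seriola dumerili,PISC,true,true
Carangidae,Trachurus spp.,PLAN,true,false
Carangidae,Pseudocaranx dentex,PLAN,true,false
Scombridae,Sarpa salpa,HERB,false,true
Scombridae,Euthynnus aletteratus,PISC,true,true
Coryphaenidae,Coryphaena hippurus,PISC,true,false
Haemulidae,Pomadasys incisus,MACRO,false,true
Haemulidae,Parapristipoma octolineatum,MACRO,false,true
Sciaenidae,Sciaena umbra,PISC,false,true
Mullidae,Mullus surmuletus,DETR,false,true
Sparidae,Boops boops,PLAN,true,true
Sparidae,Dentex dentex,PISC,false,true
Sparidae,Diplodus annularis,OMNI,false,true
Sparidae,Diplodus cervinus,OMNI,false,true
Sparidae,Diplodus puntazzo,OMNI,false,true
Sparidae,Diplodus sargus,OMNI,false,true
Sparidae,Diplodus vulgaris,OMNI,false,true
Sparidae,Oblada melanura,PLAN,true,true
Sparidae,Pagrus pagrus,OMNI,false,true
Sparidae,Pagrus auriga,OMNI,false,false
Sparidae,Sardina pilchardus,PLAN,true,true
Sparidae,Sparus aurata,OMNI,false,true
Sparidae,Spondyliosoma cantharus,OMNI,false,true
Sparidae,Spicara smaris,PLAN,true,true
Sparidae,Spicara maena,PLAN,true,true
Pomacentridae,Chromis chromis,PLAN,true,true
Labridae,Coris julis,MICRO,false,true
Labridae,Labrus merula,MICRO,false,true
Labridae,Labrus viridis,MICRO,false,true
Labridae,Symphodus dordeleini,MICRO,false,true
Labridae,Symphodus mediterraneus,MICRO,false,true
Labridae,Symphodus melanocercus,MICRO,false,true
Labridae,Symphodus ocellatus,MICRO,false,true
Labridae,Symphodus roissali,MICRO,false,true
Labridae,Symphodus cinereus,MICRO,false,true
Labridae,Symphodus rostratus,MICRO,false,true
Labridae,Symphodus tinca,MICRO,false,true
Labridae,Thalasoma pavo,MICRO,false,true
Sphyraenidae,Sphyraena viridensis,PISC,true,true
Mugilidae,Mugilidae spp.,DETR,true,true
Scorpaenidae,Scorpaena maderensis,MACRO,false,false
Scorpaenidae,Scorpaena scrofa,PISC,false,true
Scorpaenidae,Scorpaena porcus,MACRO,false,true
Scorpaenidae,Scorpaena notata,MACRO,false,true
Atherinidae,Atherina sp.,PLAN,true,false
Molidae,Mola mola,PLAN,true,false
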