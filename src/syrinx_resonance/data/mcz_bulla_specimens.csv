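species,common_name,catalog_id,side,volume_mm3,opening_diameter_mm,neck_length_mm
Aix sponsa,Wood duck,MCZ:Orn:341876,left,1240.86,5.75,0.86
Aix sponsa,Wood duck,MCZ:Orn:347504,left,1266.41,4.96,0.8
Anas fulvigula,Mottled duck,MCZ:Orn:342070,left,3197.14,6.17,1.14
Anas platyrhynchos,Mallard,MCZ:Orn:347156,left,3549.71,9.7,0.54
Anas rubripes,American black duck,MCZ:Orn:335525,left,3508.36,8.01,1.54
Anas rubripes,American black duck,MCZ:Orn:346547,left,3678.73,9.44,1.96
Aythya americana,Redhead,MCZ:Orn:346918,left,2095.85,6.03,0.87
Aythya collaris,Ring-necked duck,MCZ:Orn:341918,left,2015.66,8.27,1.88
Aythya fuligula,Tufted duck,MCZ:Orn:340385,left,1997.09,8.22,0.86
Bucephala clangula,Common goldeneye,MCZ:Orn:347155,left,5233.93,4.08,3.8
Bucephala clangula,Common goldeneye,MCZ:Orn:347155,right,1308.1,6.28,2.05
Chloephaga rubidiceps,Ruddy-headed goose,MCZ:Orn:343209,left,6744.18,6.46,1.54
Dendrocygna autumnalis,Black-bellied whistling duck,MCZ:Orn:340273,left,1055.14,2.96,1.07
Histrionicus histrionicus,Harlequin duck,MCZ:Orn:366269,left,3798.3,4.24,0.75
Histrionicus histrionicus,Harlequin duck,MCZ:Orn:336960,left,4368.48,4.56,1.33
Lophodytes cucullatus,Hooded merganser,MCZ:Orn:342699,left,1242.79,5.24,0.84
Mergus albellus,Smew,MCZ:Orn:340383,left,2214.95,5.39,1.87
Mergus serrator,Red-breasted merganser,MCZ:Orn:341891,left,6969.61,6.98,1.17
Mergus serrator,Red-breasted merganser,MCZ:Orn:341891,right,4734.47,5.93,1.18
Mergus serrator,Red-breasted merganser,MCZ:Orn:341905,left,6640.54,7.52,1.36
Mergus serrator,Red-breasted merganser,MCZ:Orn:341905,right,3956.18,6.31,1.26
Mergus serrator,Red-breasted merganser,MCZ:Orn:342835,left,8431.59,8.9,1.37
Mergus serrator,Red-breasted merganser,MCZ:Orn:342835,right,5280.2,8.9,1.84
Somateria mollissima,Common eider,MCZ:Orn:336858,left,1361.12,6.07,1.43
Somateria mollissima,Common eider,MCZ:Orn:337334,left,1439.66,7.14,1.49
Somateria mollissima,Common eider,MCZ:Orn:342589,left,1377.45,6.51,1.2
Somateria mollissima,Common eider,MCZ:Orn:342590,left,1409.08,7.62,1.15
Somateria mollissima,Common eider,MCZ:Orn:342591,left,1362.43,8.27,2.11
Tachyeres brachypterus,Falkland steamer duck,MCZ:Orn:342206,left,3296.15,8.22,1.37
Tadorna tadorna,Common shelduck,MCZ:Orn:347540,left,3694.86,8.34,1.36
Tadorna tadorna,Common shelduck,MCZ:Orn:347540,right,1772.15,8.32,1.22
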