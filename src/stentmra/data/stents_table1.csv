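stent_id,name,manufacturer,material,primary_use,diameter_mm,length_mm
1,SAXX Small,Devon,316L,Arterial vessels,5,17
2,SelfX Xpert,Abbott,nitinol,Peripheral vasculature/biliary duct,5,20
3,Palmaz Genesis,Cordis,316L,Peripheral arteries below aortic arch/biliary tree,6,39
4,Absolute,Guidant,nitinol,Biliary/peripheral vessels,7,60
5,AccuLink Carotid,Guidant,nitinol,Internal carotid and common carotid arteries,7,40
6,Express Vascular LD,Boston Scientific,316L,Peripheral vessels,7,37
7,"OmniLink 0,018",Guidant,316L,Biliary/peripheral arteries,7,18
8,"OmniLink 0,035",Guidant,316L,Biliary/peripheral arteries,7,35
9,Palmaz Corinthian IQ,Cordis,316L,Peripheral vessels,7,40
10,Renal109,Abbott,tantalum,Renal artery,7,18
11,Renal137,Abbott,tantalum,Renal artery,7,18
12,Sentinol,Boston Scientific,nitinol,Peripheral vessels,7,59
13,Symphony,Boston Scientific,nitinol,Iliac artery,7,40
14,Vascuflex SE,B. Braun,nitinol,Peripheral vessels,7,20
15,Wallstent Uni,Boston Scientific,cobalt-superalloy,Iliac artery / superficial femoral artery / tracheal,7,60
16,Zilver,Cook,nitinol,Carotid artery,7,40
17,Evo,pfm,nitinol,Pelvic arteries and peripheral vessels/biliary,8,50
18,RxCarotid,Abbott,nitinol,Carotid artery,8,30
19,SAXX Large,Devon,316L,Arterial vessels,8,35
20,Evo Target,pfm,nitinol,Intravascular/biliary,10,80
21,Wallgraft Endoprothesis,Boston Scientific,PET+cobalt-superalloy,Trachea/bronchus (off label: peripheral arteries),10,70
22,CP Stent,pfm,platinum-iridium,Aorta,13,28
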