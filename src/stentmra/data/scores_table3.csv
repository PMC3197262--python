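stent_id,name,score_si_printed,score_vis_printed,score_hom_printed,overall_score_printed,overall_class_printed
1,SAXX Small,1,1,1,3,poor
2,SelfX Xpert,3,2,2,7,intermediate
3,Palmaz Genesis,1,1,1,3,poor
4,Absolute,3,2,3,8,good
5,AccuLink Carotid,2,2,2,6,intermediate
6,Express Vascular LD,1,1,1,3,poor
7,OmniLink 0.018,2,2,2,6,intermediate
8,OmniLink 0.035,2,2,2,6,intermediate
9,Palmaz Corinthian IQ,1,1,1,3,poor
10,Renal109,3,3,2,7,good
11,Renal137,3,2,3,8,good
12,Sentinol,2,3,3,8,good
13,Symphony,1,2,2,5,intermediate
14,Vascuflex SE,2,3,3,8,good
15,Wallstent Uni,3,2,3,8,good
16,Zilver,3,2,3,8,good
17,Evo,2,3,2,7,intermediate
18,RxCarotid,1,2,1,4,poor
19,SAXX Large,1,1,1,3,poor
20,Evo Target,2,3,2,7,intermediate
21,Wallgraft Endoprothesis,2,3,2,7,intermediate
22,CP Stent,1,3,2,6,intermediate
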