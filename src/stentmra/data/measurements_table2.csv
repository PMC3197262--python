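stent_id,name,si_percent,score_si_printed,vis_min_percent,score_vis_printed,sd_over_mean,score_hom_printed
1,SAXX Small,7,1,27,1,0.43,1
2,SelfX Xpert,62,3,58,2,0.11,2
3,Palmaz Genesis,6,1,0,1,0.44,1
4,Absolute,80,3,69,2,0.06,3
5,AccuLink Carotid,57,2,69,2,0.10,2
6,Express Vascular LD,21,1,0,1,0.48,1
7,"OmniLink 0,018",46,2,38,2,0.33,2
8,"OmniLink 0,035",45,2,51,2,0.21,2
9,Palmaz Corinthian IQ,12,1,0,1,0.42,1
10,Renal109,66,3,72,3,0.16,2
11,Renal137,69,3,58,2,0.07,3
12,Sentinol,51,2,89,3,0.04,3
13,Symphony,15,1,60,2,0.35,2
14,Vascuflex SE,42,2,80,3,0.09,3
15,Wallstent Uni,117,3,60,2,0.08,3
16,Zilver,66,3,66,2,0.07,3
17,Evo,45,2,80,3,0.19,2
18,RxCarotid,10,1,65,2,0.81,1
19,SAXX Large,7,1,0,1,0.40,1
20,Evo Target,43,2,92,3,0.16,2
21,Wallgraft Endoprothesis,52,2,75,3,0.16,2
22,CP Stent,21,1,86,3,0.14,2
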