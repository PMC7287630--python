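aal_id,name,hemisphere,day1_START,day1_STOPP,day1_POTS,day2_START,day2_STOPP,day2_POTS
5,Frontal_Sup_Orb_L,L,0.0211,-0.0407,0.0181,,,
9,Frontal_Mid_Orb_L,L,0.0164,-0.1065,0.0126,-0.4932,0.0184,0.0305
11,Frontal_Inf_Oper_L,L,-0.105,-0.1363,0.2162,,,
7,Frontal_Mid_L,L,-0.0231,0.0383,-0.0026,-0.0147,0.0587,-0.0739
3,Frontal_Sup_L,L,-0.0512,-0.1179,0.1449,0.1265,-0.1338,0.1886
19,Supp_Motor_Area_L,L,0.1117,-0.0605,0.0136,-0.1579,-0.0389,0.0982
69,Paracentral_Lobule_L,L,-0.1134,0.1053,-0.0204,-0.2408,-0.3127,0.3879
1,Precentral_L,L,0.0928,-0.0498,-0.0864,,,
57,Postcentral_L,L,0.0961,0.0871,-0.2163,0.3113,0.2695,-0.2883
63,SupraMarginal_L,L,0.0877,-0.1433,-0.1304,-0.071,0.1057,-0.0139
65,Angular_L,L,-0.0895,0.0158,0.1133,0.2232,0.0589,-0.0733
51,Occipital_Mid_L,L,-0.0548,0.1066,-0.0938,0.0097,0.0655,-0.0653
43,Calcarine_L,L,-0.0111,-0.0567,0.0071,,,
83,Temporal_Pole_Sup_L,L,-0.1597,0.1995,-0.1059,,,
81,Temporal_Sup_L,L,-0.088,-0.0438,0.2625,-0.0577,-0.2622,0.1185
89,Temporal_Inf_L,L,-0.076,-0.0125,-0.0124,0.0575,0.0984,-0.1835
31,Cingulum_Ant_L,L,0.0566,0.0959,-0.0963,,,
33,Cingulum_Mid_L,L,0.0297,0.0179,0.0812,0.1534,-0.2875,0.2176
71,Caudate_L,L,-0.0058,0.0442,-0.0503,,,
75,Pallidum_L,L,-0.0224,-0.0114,0.0408,,,
93,Cerebellum_Crus2_L,L,-0.0164,0.1204,-0.1847,-0.3072,-0.0044,0.2066
99,Cerebellum_6_L,L,0.0299,0.0562,-0.1019,0.2718,-0.1082,-0.0449
103,Cerebellum_8_L,L,-0.0598,0.0566,-0.1381,-0.2062,0.0697,-0.1023
30,Insula_R,R,-0.0488,0.0077,-0.1392,0.0386,0.1679,-0.1451
26,Frontal_Med_Orb_R,R,-0.0304,0.0593,-0.0612,,,
16,Frontal_Inf_Orb_R,R,-0.065,0.0401,0.021,-0.1562,0.2341,-0.1199
10,Frontal_Mid_Orb_R,R,0.0037,-0.0985,0.1253,0.1542,-0.0252,-0.1217
6,Frontal_Sup_Orb_R,R,0.0092,0.0779,0.0805,,,
14,Frontal_Inf_Tri_R,R,0.0015,-0.0007,0.0023,-0.2509,-0.2165,0.2417
4,Frontal_Sup_R,R,0.0175,-0.0247,-0.0211,0.0231,-0.2045,0.126
24,Frontal_Sup_Medial_R,R,0.0033,0.0112,-0.1266,-0.4661,0.0834,0.0898
20,Supp_Motor_Area_R,R,-0.1253,0.0302,0.1129,0.0463,0.0231,-0.1466
2,Precentral_R,R,-0.0915,0.058,0.0434,0.0509,0.113,-0.0868
58,Postcentral_R,R,0.0028,-0.1191,0.0851,,,
18,Rolandic_Oper_R,R,0.0442,-0.0095,-0.016,0.0634,-0.1134,-0.0481
54,Occipital_Inf_R,R,0.005,-0.0153,-0.0269,,,
48,Lingual_R,R,0.0194,-0.0209,0.0209,0.2479,0.0873,-0.0667
56,Fusiform_R,R,-0.0112,-0.0652,0.1056,,,
82,Temporal_Sup_R,R,-0.0268,0.0053,-0.062,-0.0754,0.3209,-0.1277
34,Cingulum_Mid_R,R,0.1826,0.0308,-0.166,0.2548,0.0095,-0.088
36,Cingulum_Post_R,R,-0.0018,0.0007,0.019,,,
72,Caudate_R,R,-0.0057,0.0647,0.0026,,,
100,Cerebellum_6_R,R,-0.1639,0.0832,0.0797,,,
102,Cerebellum_7b_R,R,-0.0342,-0.051,0.1401,-0.2785,-0.0127,0.0302
104,Cerebellum_8_R,R,-0.072,-0.0188,0.089,-0.1158,-0.118,0.1482
106,Cerebellum_9_R,R,-0.0155,0.0817,-0.1665,,,
111,Vermis_4_5,z,-0.0042,-0.0033,-0.0763,,,
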