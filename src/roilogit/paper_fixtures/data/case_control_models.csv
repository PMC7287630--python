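aal_id,name,hemisphere,day1,day2
77,Thalamus_L,L,,-0.2715
78,Thalamus_R,R,-0.1715,0.0304
91,Cerebellum_Crus1_L,L,-0.0297,-0.0707
101,Cerebellum_7b_L,L,0.5321,
103,Cerebellum_8_L,L,-0.4121,
93,Cerebellum_Crus2_L,L,,0.0672
97,Cerebellum_4_5_L,L,,0.7197
94,Cerebellum_Crus2_R,R,-0.2809,
100,Cerebellum_6_R,R,0.0264,
92,Cerebellum_Crus1_R,R,,0.0134
102,Cerebellum_7b_R,R,,0.1074
104,Cerebellum_8_R,R,,-0.0562
110,Vermis_3,z,,-0.7653
115,Vermis_9,z,,0.6321
63,SupraMarginal_L,L,0.1442,0.0213
83,Temporal_Pole_Sup_L,L,0.038,-0.0213
9,Frontal_Mid_Orb_L,L,0.2989,
3,Frontal_Sup_L,L,-0.0646,
13,Frontal_Inf_Tri_L,L,0.0494,
57,Postcentral_L,L,-0.1314,
81,Temporal_Sup_L,L,0.5282,
45,Cuneus_L,L,0.046,
43,Calcarine_L,L,0.7595,
23,Frontal_Sup_Medial_L,L,,-0.0385
33,Cingulum_Mid_L,L,,0.0945
17,Rolandic_Oper_L,L,,0.0205
39,ParaHippocampal_L,L,,0.9032
30,Insula_R,R,-0.0368,-0.0131
10,Frontal_Mid_Orb_R,R,-0.0168,0.0382
6,Frontal_Sup_Orb_R,R,0.0627,0.0245
70,Paracentral_Lobule_R,R,-0.4414,-0.2976
44,Calcarine_R,R,-0.805,-0.0535
84,Temporal_Pole_Sup_R,R,-0.3209,0.2698
28,Rectus_R,R,-0.366,
12,Frontal_Inf_Oper_R,R,-0.052,
20,Supp_Motor_Area_R,R,-0.0422,
2,Precentral_R,R,0.1018,
66,Angular_R,R,0.0399,
46,Cuneus_R,R,-0.1037,
52,Occipital_Mid_R,R,-0.0461,
48,Lingual_R,R,-0.3924,
32,Cingulum_Ant_R,R,,-0.0409
22,Olfactory_R,R,,-0.4417
24,Frontal_Sup_Medial_R,R,,0.0653
58,Postcentral_R,R,,-0.0247
50,Occipital_Sup_R,R,,-0.0219
88,Temporal_Pole_Mid_R,R,,-0.3901
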