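index,name,abbrev,hemisphere,lobe
1,Precentral Gyrus,PreCG,L,frontal
2,Precentral Gyrus,PreCG,R,frontal
3,Superior Frontal Gyrus,SFGdor,L,frontal
4,Superior Frontal Gyrus,SFGdor,R,frontal
5,Superior Orbital Frontal Gyrus,ORBsup,L,frontal
6,Superior Orbital Frontal Gyrus,ORBsup,R,frontal
7,Middle Frontal Gyrus,MFG,L,frontal
8,Middle Frontal Gyrus,MFG,R,frontal
9,Middle Orbital Frontal Gyrus,ORBmid,L,frontal
10,Middle Orbital Frontal Gyrus,ORBmid,R,frontal
11,Inferior Opercular Frontal Gyrus,IFGoperc,L,frontal
12,Inferior Opercular Frontal Gyrus,IFGoperc,R,frontal
13,Inferior Triangular Frontal Gyrus,IFGtriang,L,frontal
14,Inferior Triangular Frontal Gyrus,IFGtriang,R,frontal
15,Inferior Orbital Frontal Gyrus,ORBinf,L,frontal
16,Inferior Orbital Frontal Gyrus,ORBinf,R,frontal
17,Rolandic Operculum,ROL,L,frontal
18,Rolandic Operculum,ROL,R,frontal
19,Supplementary Motor Area,SMA,L,frontal
20,Supplementary Motor Area,SMA,R,frontal
21,Olfactory Cortex,OLF,L,limbic
22,Olfactory Cortex,OLF,R,limbic
23,Medial Superior Frontal Gyrus,SFGmed,L,frontal
24,Medial Superior Frontal Gyrus,SFGmed,R,frontal
25,Medial Orbital Frontal Gyrus,ORBsupmed,L,frontal
26,Medial Orbital Frontal Gyrus,ORBsupmed,R,frontal
27,Gyrus Rectus,REC,L,frontal
28,Gyrus Rectus,REC,R,frontal
29,Insula,INS,L,limbic
30,Insula,INS,R,limbic
31,Anterior Cingulate Gyrus,ACG,L,limbic
32,Anterior Cingulate Gyrus,ACG,R,limbic
33,Middle Cingulate Gyrus,DCG,L,limbic
34,Middle Cingulate Gyrus,DCG,R,limbic
35,Posterior Cingulate Gyrus,PCG,L,limbic
36,Posterior Cingulate Gyrus,PCG,R,limbic
37,Hippocampus,HIP,L,limbic
38,Hippocampus,HIP,R,limbic
39,Parahippocampal Gyrus,PHG,L,limbic
40,Parahippocampal Gyrus,PHG,R,limbic
41,Amygdala,AMYG,L,limbic
42,Amygdala,AMYG,R,limbic
43,Calcarine Cortex,CAL,L,occipital
44,Calcarine Cortex,CAL,R,occipital
45,Cuneus,CUN,L,occipital
46,Cuneus,CUN,R,occipital
47,Lingual Gyrus,LING,L,occipital
48,Lingual Gyrus,LING,R,occipital
49,Superior Occipital Gyrus,SOG,L,occipital
50,Superior Occipital Gyrus,SOG,R,occipital
51,Middle Occipital Gyrus,MOG,L,occipital
52,Middle Occipital Gyrus,MOG,R,occipital
53,Inferior Occipital Gyrus,IOG,L,occipital
54,Inferior Occipital Gyrus,IOG,R,occipital
55,Fusiform Gyrus,FFG,L,temporal
56,Fusiform Gyrus,FFG,R,temporal
57,Postcentral Gyrus,PoCG,L,parietal
58,Postcentral Gyrus,PoCG,R,parietal
59,Superior Parietal Gyrus,SPG,L,parietal
60,Superior Parietal Gyrus,SPG,R,parietal
61,Inferior Parietal Lobule,IPL,L,parietal
62,Inferior Parietal Lobule,IPL,R,parietal
63,Supramarginal Gyrus,SMG,L,parietal
64,Supramarginal Gyrus,SMG,R,parietal
65,Angular Gyrus,ANG,L,parietal
66,Angular Gyrus,ANG,R,parietal
67,Precuneus,PCUN,L,parietal
68,Precuneus,PCUN,R,parietal
69,Paracentral Lobule,PCL,L,parietal
70,Paracentral Lobule,PCL,R,parietal
71,Caudate Nucleus,CAU,L,limbic
72,Caudate Nucleus,CAU,R,limbic
73,Putamen,PUT,L,limbic
74,Putamen,PUT,R,limbic
75,Pallidum,PAL,L,limbic
76,Pallidum,PAL,R,limbic
77,Thalamus,THA,L,limbic
78,Thalamus,THA,R,limbic
79,Heschl Gyrus,HES,L,temporal
80,Heschl Gyrus,HES,R,temporal
81,Superior Temporal Gyrus,STG,L,temporal
82,Superior Temporal Gyrus,STG,R,temporal
83,Superior Temporal Pole,TPOsup,L,temporal
84,Superior Temporal Pole,TPOsup,R,temporal
85,Middle Temporal Gyrus,MTG,L,temporal
86,Middle Temporal Gyrus,MTG,R,temporal
87,Middle Temporal Pole,TPOmid,L,temporal
88,Middle Temporal Pole,TPOmid,R,temporal
89,Inferior Temporal Gyrus,ITG,L,temporal
90,Inferior Temporal Gyrus,ITG,R,temporal
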