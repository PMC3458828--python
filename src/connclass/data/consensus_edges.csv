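index_a,index_b,network,subnetwork,mean_p
3,7,Cortical-Limbic,frontal-limbic,9.11e-05
3,29,Cortical-Limbic,frontal-limbic,2.05e-04
5,9,Cortical-Limbic,frontal-limbic,6.49e-05
5,37,Cortical-Limbic,frontal-limbic,8.57e-05
5,73,Cortical-Limbic,frontal-limbic,3.39e-04
9,15,Cortical-Limbic,frontal-limbic,2.16e-04
9,37,Cortical-Limbic,frontal-limbic,1.07e-04
9,73,Cortical-Limbic,frontal-limbic,2.02e-04
9,75,Cortical-Limbic,frontal-limbic,3.57e-04
13,15,Cortical-Limbic,frontal-limbic,2.28e-04
15,29,Cortical-Limbic,frontal-limbic,6.85e-07
15,77,Cortical-Limbic,frontal-limbic,2.47e-04
25,32,Cortical-Limbic,frontal-limbic,3.52e-04
32,34,Cortical-Limbic,frontal-limbic,3.92e-05
19,73,Cortical-Limbic,frontal-limbic,1.51e-04
20,32,Cortical-Limbic,frontal-limbic,1.44e-04
37,77,Cortical-Limbic,frontal-limbic,1.83e-04
72,78,Cortical-Limbic,frontal-limbic,1.76e-04
75,77,Cortical-Limbic,frontal-limbic,3.46e-04
30,60,Cortical-Limbic,parietal-limbic,2.26e-05
36,60,Cortical-Limbic,parietal-limbic,3.07e-04
36,68,Cortical-Limbic,parietal-limbic,7.61e-05
60,74,Cortical-Limbic,parietal-limbic,1.15e-05
60,66,Cortical-Limbic,parietal-limbic,3.97e-04
67,70,Cortical-Limbic,parietal-limbic,2.12e-05
55,77,Cortical-Limbic,temporal-limbic,4.73e-05
37,85,Cortical-Limbic,temporal-limbic,2.15e-04
37,89,Cortical-Limbic,temporal-limbic,1.88e-04
38,90,Cortical-Limbic,temporal-limbic,1.96e-04
44,90,Occipital-Temporal,,2.20e-04
50,52,Occipital-Temporal,,3.26e-04
50,90,Occipital-Temporal,,5.85e-05
52,90,Occipital-Temporal,,4.16e-04
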