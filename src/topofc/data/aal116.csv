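index,name,abbreviation,hemisphere,division
1,"Left precentral gyrus",PreCG.L,L,cerebrum
2,"Right precentral gyrus",PreCG.R,R,cerebrum
3,"Left superior frontal gyrus, dorsolateral",SFGdor.L,L,cerebrum
4,"Right superior frontal gyrus, dorsolateral",SFGdor.R,R,cerebrum
5,"Left superior frontal gyrus, orbital part",ORBsup.L,L,cerebrum
6,"Right superior frontal gyrus, orbital part",ORBsup.R,R,cerebrum
7,"Left middle frontal gyrus",MFG.L,L,cerebrum
8,"Right middle frontal gyrus",MFG.R,R,cerebrum
9,"Left middle frontal gyrus, orbital part",ORBmid.L,L,cerebrum
10,"Right middle frontal gyrus, orbital part",ORBmid.R,R,cerebrum
11,"Left inferior frontal gyrus, opercular part",IFGoperc.L,L,cerebrum
12,"Right inferior frontal gyrus, opercular part",IFGoperc.R,R,cerebrum
13,"Left inferior frontal gyrus, triangular part",IFGtriang.L,L,cerebrum
14,"Right inferior frontal gyrus, triangular part",IFGtriang.R,R,cerebrum
15,"Left inferior frontal gyrus, orbital part",ORBinf.L,L,cerebrum
16,"Right inferior frontal gyrus, orbital part",ORBinf.R,R,cerebrum
17,"Left rolandic operculum",ROL.L,L,cerebrum
18,"Right rolandic operculum",ROL.R,R,cerebrum
19,"Left supplementary motor area",SMA.L,L,cerebrum
20,"Right supplementary motor area",SMA.R,R,cerebrum
21,"Left olfactory cortex",OLF.L,L,cerebrum
22,"Right olfactory cortex",OLF.R,R,cerebrum
23,"Left superior frontal gyrus, medial",SFGmed.L,L,cerebrum
24,"Right superior frontal gyrus, medial",SFGmed.R,R,cerebrum
25,"Left superior frontal gyrus, medial orbital",ORBsupmed.L,L,cerebrum
26,"Right superior frontal gyrus, medial orbital",ORBsupmed.R,R,cerebrum
27,"Left gyrus rectus",REC.L,L,cerebrum
28,"Right gyrus rectus",REC.R,R,cerebrum
29,"Left insula",INS.L,L,cerebrum
30,"Right insula",INS.R,R,cerebrum
31,"Left anterior cingulate and paracingulate gyri",ACG.L,L,cerebrum
32,"Right anterior cingulate and paracingulate gyri",ACG.R,R,cerebrum
33,"Left median cingulate and paracingulate gyri",DCG.L,L,cerebrum
34,"Right median cingulate and paracingulate gyri",DCG.R,R,cerebrum
35,"Left posterior cingulate gyrus",PCG.L,L,cerebrum
36,"Right posterior cingulate gyrus",PCG.R,R,cerebrum
37,"Left hippocampus",HIP.L,L,cerebrum
38,"Right hippocampus",HIP.R,R,cerebrum
39,"Left parahippocampal gyrus",PHG.L,L,cerebrum
40,"Right parahippocampal gyrus",PHG.R,R,cerebrum
41,"Left amygdala",AMYG.L,L,cerebrum
42,"Right amygdala",AMYG.R,R,cerebrum
43,"Left calcarine fissure and surrounding cortex",CAL.L,L,cerebrum
44,"Right calcarine fissure and surrounding cortex",CAL.R,R,cerebrum
45,"Left cuneus",CUN.L,L,cerebrum
46,"Right cuneus",CUN.R,R,cerebrum
47,"Left lingual gyrus",LING.L,L,cerebrum
48,"Right lingual gyrus",LING.R,R,cerebrum
49,"Left superior occipital gyrus",SOG.L,L,cerebrum
50,"Right superior occipital gyrus",SOG.R,R,cerebrum
51,"Left middle occipital gyrus",MOG.L,L,cerebrum
52,"Right middle occipital gyrus",MOG.R,R,cerebrum
53,"Left inferior occipital gyrus",IOG.L,L,cerebrum
54,"Right inferior occipital gyrus",IOG.R,R,cerebrum
55,"Left fusiform gyrus",FFG.L,L,cerebrum
56,"Right fusiform gyrus",FFG.R,R,cerebrum
57,"Left postcentral gyrus",PoCG.L,L,cerebrum
58,"Right postcentral gyrus",PoCG.R,R,cerebrum
59,"Left superior parietal gyrus",SPG.L,L,cerebrum
60,"Right superior parietal gyrus",SPG.R,R,cerebrum
61,"Left inferior parietal gyrus",IPL.L,L,cerebrum
62,"Right inferior parietal gyrus",IPL.R,R,cerebrum
63,"Left supramarginal gyrus",SMG.L,L,cerebrum
64,"Right supramarginal gyrus",SMG.R,R,cerebrum
65,"Left angular gyrus",ANG.L,L,cerebrum
66,"Right angular gyrus",ANG.R,R,cerebrum
67,"Left precuneus",PCUN.L,L,cerebrum
68,"Right precuneus",PCUN.R,R,cerebrum
69,"Left paracentral lobule",PCL.L,L,cerebrum
70,"Right paracentral lobule",PCL.R,R,cerebrum
71,"Left caudate nucleus",CAU.L,L,cerebrum
72,"Right caudate nucleus",CAU.R,R,cerebrum
73,"Left putamen",PUT.L,L,cerebrum
74,"Right putamen",PUT.R,R,cerebrum
75,"Left pallidum",PAL.L,L,cerebrum
76,"Right pallidum",PAL.R,R,cerebrum
77,"Left thalamus",THA.L,L,cerebrum
78,"Right thalamus",THA.R,R,cerebrum
79,"Left heschl gyrus",HES.L,L,cerebrum
80,"Right heschl gyrus",HES.R,R,cerebrum
81,"Left superior temporal gyrus",STG.L,L,cerebrum
82,"Right superior temporal gyrus",STG.R,R,cerebrum
83,"Left temporal pole: superior temporal gyrus",TPOsup.L,L,cerebrum
84,"Right temporal pole: superior temporal gyrus",TPOsup.R,R,cerebrum
85,"Left middle temporal gyrus",MTG.L,L,cerebrum
86,"Right middle temporal gyrus",MTG.R,R,cerebrum
87,"Left temporal pole: middle temporal gyrus",TPOmid.L,L,cerebrum
88,"Right temporal pole: middle temporal gyrus",TPOmid.R,R,cerebrum
89,"Left inferior temporal gyrus",ITG.L,L,cerebrum
90,"Right inferior temporal gyrus",ITG.R,R,cerebrum
91,"Left cerebellum crus 1",CRBLCrus1.L,L,cerebellum
92,"Right cerebellum crus 1",CRBLCrus1.R,R,cerebellum
93,"Left cerebellum crus 2",CRBLCrus2.L,L,cerebellum
94,"Right cerebellum crus 2",CRBLCrus2.R,R,cerebellum
95,"Left cerebellum 3",CRBL3.L,L,cerebellum
96,"Right cerebellum 3",CRBL3.R,R,cerebellum
97,"Left cerebellum 4-5",CRBL45.L,L,cerebellum
98,"Right cerebellum 4-5",CRBL45.R,R,cerebellum
99,"Left cerebellum 6",CRBL6.L,L,cerebellum
100,"Right cerebellum 6",CRBL6.R,R,cerebellum
101,"Left cerebellum 7b",CRBL7b.L,L,cerebellum
102,"Right cerebellum 7b",CRBL7b.R,R,cerebellum
103,"Left cerebellum 8",CRBL8.L,L,cerebellum
104,"Right cerebellum 8",CRBL8.R,R,cerebellum
105,"Left cerebellum 9",CRBL9.L,L,cerebellum
106,"Right cerebellum 9",CRBL9.R,R,cerebellum
107,"Left cerebellum 10",CRBL10.L,L,cerebellum
108,"Right cerebellum 10",CRBL10.R,R,cerebellum
109,"Vermis 1-2",Vermis12,M,cerebellum
110,"Vermis 3",Vermis3,M,cerebellum
111,"Vermis 4-5",Vermis45,M,cerebellum
112,"Vermis 6",Vermis6,M,cerebellum
113,"Vermis 7",Vermis7,M,cerebellum
114,"Vermis 8",Vermis8,M,cerebellum
115,"Vermis 9",Vermis9,M,cerebellum
116,"Vermis 10",Vermis10,M,cerebellum
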