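index,name,hemisphere,lobe,pair_index
0,lh_bankssts,left,temporal,0
1,lh_caudalanteriorcingulate,left,cingulate,1
2,lh_caudalmiddlefrontal,left,frontal,2
3,lh_cuneus,left,occipital,3
4,lh_entorhinal,left,temporal,4
5,lh_fusiform,left,temporal,5
6,lh_inferiorparietal,left,parietal,6
7,lh_inferiortemporal,left,temporal,7
8,lh_isthmuscingulate,left,cingulate,8
9,lh_lateraloccipital,left,occipital,9
10,lh_lateralorbitofrontal,left,frontal,10
11,lh_lingual,left,occipital,11
12,lh_medialorbitofrontal,left,frontal,12
13,lh_middletemporal,left,temporal,13
14,lh_parahippocampal,left,temporal,14
15,lh_paracentral,left,frontal,15
16,lh_parsopercularis,left,frontal,16
17,lh_parsorbitalis,left,frontal,17
18,lh_parstriangularis,left,frontal,18
19,lh_pericalcarine,left,occipital,19
20,lh_postcentral,left,parietal,20
21,lh_posteriorcingulate,left,cingulate,21
22,lh_precentral,left,frontal,22
23,lh_precuneus,left,parietal,23
24,lh_rostralanteriorcingulate,left,cingulate,24
25,lh_rostralmiddlefrontal,left,frontal,25
26,lh_superiorfrontal,left,frontal,26
27,lh_superiorparietal,left,parietal,27
28,lh_superiortemporal,left,temporal,28
29,lh_supramarginal,left,parietal,29
30,lh_frontalpole,left,frontal,30
31,lh_temporalpole,left,temporal,31
32,lh_transversetemporal,left,temporal,32
33,lh_insula,left,insula,33
34,rh_bankssts,right,temporal,0
35,rh_caudalanteriorcingulate,right,cingulate,1
36,rh_caudalmiddlefrontal,right,frontal,2
37,rh_cuneus,right,occipital,3
38,rh_entorhinal,right,temporal,4
39,rh_fusiform,right,temporal,5
40,rh_inferiorparietal,right,parietal,6
41,rh_inferiortemporal,right,temporal,7
42,rh_isthmuscingulate,right,cingulate,8
43,rh_lateraloccipital,right,occipital,9
44,rh_lateralorbitofrontal,right,frontal,10
45,rh_lingual,right,occipital,11
46,rh_medialorbitofrontal,right,frontal,12
47,rh_middletemporal,right,temporal,13
48,rh_parahippocampal,right,temporal,14
49,rh_paracentral,right,frontal,15
50,rh_parsopercularis,right,frontal,16
51,rh_parsorbitalis,right,frontal,17
52,rh_parstriangularis,right,frontal,18
53,rh_pericalcarine,right,occipital,19
54,rh_postcentral,right,parietal,20
55,rh_posteriorcingulate,right,cingulate,21
56,rh_precentral,right,frontal,22
57,rh_precuneus,right,parietal,23
58,rh_rostralanteriorcingulate,right,cingulate,24
59,rh_rostralmiddlefrontal,right,frontal,25
60,rh_superiorfrontal,right,frontal,26
61,rh_superiorparietal,right,parietal,27
62,rh_superiortemporal,right,temporal,28
63,rh_supramarginal,right,parietal,29
64,rh_frontalpole,right,frontal,30
65,rh_temporalpole,right,temporal,31
66,rh_transversetemporal,right,temporal,32
67,rh_insula,right,insula,33
68,lh_thalamus,left,subcortical,34
69,lh_caudate,left,subcortical,35
70,lh_putamen,left,subcortical,36
71,lh_pallidum,left,subcortical,37
72,lh_hippocampus,left,subcortical,38
73,lh_amygdala,left,subcortical,39
74,lh_accumbens,left,subcortical,40
75,lh_ventraldc,left,subcortical,41
76,rh_thalamus,right,subcortical,34
77,rh_caudate,right,subcortical,35
78,rh_putamen,right,subcortical,36
79,rh_pallidum,right,subcortical,37
80,rh_hippocampus,right,subcortical,38
81,rh_amygdala,right,subcortical,39
82,rh_accumbens,right,subcortical,40
83,rh_ventraldc,right,subcortical,41
84,brainstem,midline,brainstem,
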