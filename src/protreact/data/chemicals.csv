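index,name,cas,human_category,domain,prohapten_flag,pr_cys,pr_lys,pr_mean,dpra_cys,dpra_lys,dpra_mean
1,"2,4-Dinitrochlorobenzene",97-00-7,1,,,62.0,53.6,57.8,100.0,14.7,57.4
2,Methylisothiazolinone,2682-20-4,1,,,10.0,0.0,5.0,97.9,0.0,49.0
3,"1,4-Phenylenediamine",106-50-3,1,,,22.3,32.3,27.3,93.0,23.5,58.3
4,Tetrachlorosalicylanilide,1154-59-2,1,,,51.0,80.8,65.9,36.8,9.0,22.9
5,Dimethyl fumarate,624-49-7,1,,,97.0,8.0,52.5,100.0,42.9,71.5
6,Diphencyclopropenone,886-38-4,1,,,6.3,29.8,18.0,98.8,0.0,49.4
7,Benzisothiazolinone,2634-33-5,2,,,86.0,25.3,55.6,97.7,9.7,53.7
8,Cinnamic aldehyde,104-55-2,2,,,54.5,32.0,43.3,70.6,43.3,57.0
9,Diethyl maleate,141-05-9,2,,,67.5,16.8,42.1,100.0,85.5,92.8
10,3-Dimethylaminopropylamine,109-55-7,2,,,0.0,0.0,0.0,10.2,0.0,5.1
11,Formaldehyde,50-00-0,2,,,13.7,40.0,26.8,60.4,11.2,35.8
12,Glutaraldehyde,111-30-8,2,,,43.3,63.0,53.1,30.2,85.4,57.8
13,Glyoxal,107-22-2,2,,,24.0,42.0,33.0,92.6,88.9,90.8
14,Lyral,31906-04-4,2,,,39.4,0.0,19.7,39.4,3.4,21.4
15,Isoeugenol,97-54-1,2,,,100.0,23.0,61.5,89.3,10.7,50.0
16,Lauryl gallate,1166-52-5,2,,,93.8,83.3,88.5,90.9,8.7,49.8
17,Methyl heptine carbonate,111-12-6,2,,,39.3,0.0,19.7,97.2,0.0,48.6
18,Methyldibromo glutaronitrile,35691-65-7,2,,,81.2,47.0,64.1,100.0,28.6,64.3
19,"2-Nitro-1,4-phenylenediamine",5307-14-2,2,,,49.6,42.8,46.2,93.3,0.0,46.7
20,Propyl gallate,121-79-9,2,,,20.8,44.0,32.4,59.9,26.6,43.3
21,Thioglycerol,96-27-5,2,,,0.0,0.0,0.0,27.3,28.4,27.9
22,Toluene diamine sulfate,615-50-9,2,,,72.0,96.0,84.0,78.4,15.0,46.7
23,Methyl 2-nonynoate,111-80-8,2,,,100.0,4.9,52.4,100.0,3.2,51.6
24,2-Methoxy-4-methylphenol,93-51-6,2,,,9.5,5.6,7.6,0.0,11.5,5.8
25,Trans-2-hexenal,6728-26-3,2,,,86.0,25.0,55.5,97.9,3.6,50.8
26,2-Aminophenol,95-55-6,2,,,35.7,40.0,37.9,96.2,18.1,57.2
27,Abietic acid,514-10-3,3,,,63.3,29.5,46.4,99.9,16.3,58.1
28,Benzoyl peroxide,94-36-0,3,,,92.7,87.7,90.2,100.0,81.3,90.7
29,Bisphenol A diglycidyl ether,1675-54-3,3,,,48.0,8.7,28.4,39.4,3.4,21.4
30,Butyl glycidyl ether,2426-08-6,3,,,43.0,0.0,21.5,67.3,11.5,39.4
31,Chlorpromazine,50-53-3,3,,,39.5,21.0,30.3,-19.6,0.0,-9.8
32,Cinnamic alcohol,104-54-1,3,,,14.2,0.0,7.1,0.0,15.1,7.6
33,Citral,5392-40-5,3,,,29.0,52.7,40.8,85.7,16.9,51.3
34,Coumarin,91-64-5,3,,,4.7,0.0,2.3,1.0,0.0,0.5
35,Ethylene diamine,107-15-3,3,,,3.0,0.0,1.5,3.4,0.0,1.7
36,Eugenol,97-53-0,3,,,21.8,2.0,11.9,9.2,19.2,14.2
37,Farnesol,4602-84-0,3,,,37.0,24.0,30.5,7.3,0.0,3.7
38,Glyceryl monothioglycolate,30618-84-9,3,,,0.0,0.0,0.0,0.6,18.6,9.6
39,"1,4-Dihydroquinone",123-31-9,3,,,77.3,37.0,57.2,83.3,51.1,67.2
40,Imidazolidinyl urea,39236-46-9,3,,,16.0,52.8,34.4,52.3,1.3,26.8
41,2-Mercaptobenzothiazole,149-30-4,3,,,8.3,17.0,12.6,97.5,0.0,48.8
42,"5-Methyl-2,3-hexanedione",13706-86-0,3,,,10.5,0.0,5.3,25.8,7.5,16.7
43,Metol,55-55-0,3,,,60.0,48.3,54.1,100.0,44.7,72.4
44,Penicillin G,61-33-6,3,,,1.5,0.0,0.8,14.3,0.0,7.2
45,Phenyl benzoate,93-99-2,3,,,17.0,0.0,8.5,36.8,19.6,28.2
46,Tetramethylthiuram disulfide,137-26-8,3,,,100.0,6.0,53.0,99.5,6.9,53.2
47,3-Propylidenephthalide,17369-59-4,3,,,86.0,82.0,84.0,14.3,30.6,22.5
48,Allyl phenoxyacetate,7493-74-5,3,,,12.6,0.0,6.3,0.6,4.1,2.3
49,Cinnamyl nitrile,1885-38-7,3,,,16.6,10.9,13.7,4.0,0.0,2.0
50,Phenylacetaldehyde,122-78-1,3,,,100.0,32.0,66.0,60.7,22.6,41.7
51,Dibenzyl ether,103-50-4,4,,,95.8,80.0,47.9,11.3,0.0,5.7
52,Benzyl alcohol,100-51-6,4,,,0.5,0.0,0.3,0.0,0.0,0.0
53,Amyl cinnamic aldehyde,122-40-7,4,,,24.0,0.0,12.0,0.6,3.9,2.2
54,Amylcinnamyl alcohol,101-85-9,4,,,8.8,5.3,7.0,5.0,0.0,2.5
55,Aniline,62-53-3,4,,,3.3,3.0,3.1,0.0,9.7,4.9
56,Benzocaine,94-09-7,4,,,2.3,2.0,2.1,29.2,0.0,14.6
57,Carvone,6485-40-1,4,,,19.3,0.0,9.6,25.1,0.6,12.9
58,Ethyl acrylate,140-88-5,4,,,82.8,7.0,44.9,96.4,93.7,95.1
59,Ethyleneglycol dimethacrylate,97-90-5,4,,,22.6,15.5,19.1,87.3,12.4,49.8
60,Geraniol,106-24-1,4,,,0.8,0.0,0.4,0.0,10.0,5.0
61,Hexyl salicylate,6259-76-3,4,,,2.0,0.0,1.0,3.9,1.4,2.7
62,Hydroxycitronellal,107-75-5,4,,,5.0,3.8,4.4,17.5,6.5,12.0
63,Iodopropynyl butyl carbamate,55406-53-6,4,,,85.3,3.3,44.3,99.7,0.0,49.9
64,Lilial,80-54-6,4,,,52.0,17.0,34.5,14.0,0.7,7.4
65,Linalool,78-70-6,4,,,22.3,0.0,11.1,0.0,7.9,4.0
66,Methylmethacrylate,80-62-6,4,,,4.8,0.0,2.4,36.7,10.0,23.4
67,Resorcinol,108-46-3,4,,,1.0,0.0,0.5,1.6,0.0,0.8
68,α-Methyl cinnamic aldehyde,101-39-3,4,,,20.8,5.1,13.0,10.4,28.8,19.6
69,"β,β,3-Trimethyl benzenepropanol",103694-68-4,4,,,22.6,0.0,11.3,0.1,1.4,0.8
70,Benzyl cinnamate,103-41-3,4,,,15.7,0.0,7.9,2.2,3.2,2.7
71,Isocyclocitral,1335-66-6,4,,,30.3,0.0,15.2,15.9,42.4,29.1
72,Anethole,104-46-1,5,,,40.8,0.0,20.4,0.0,9.6,4.8
73,Anisyl alcohol,105-13-5,5,,,0.0,3.5,1.8,35.5,100.0,67.8
74,Benzyl benzoate,120-51-4,5,,,6.0,0.0,3.0,0.2,3.0,1.6
75,Benzyl salicylate,118-58-1,5,,,4.8,3.0,3.9,3.8,1.5,2.7
76,Citronellol,106-22-9,5,,,17.3,0.0,8.6,14.4,0.0,7.2
77,Hexyl cinnamic aldehyde,101-86-0,5,,,0.0,18.0,9.0,0.0,0.0,0.0
78,Isopropyl myristate,110-27-0,5,,,0.0,0.0,0.0,0.8,0.0,0.4
79,Limonene,5989-27-5,5,,,43.8,0.0,21.9,4.9,1.3,3.1
80,Pentachlorophenol,87-86-5,5,,,0.0,35.0,17.5,0.0,14.5,7.3
81,Propyl paraben,94-13-3,5,,,1.2,0.0,0.6,8.2,0.0,4.1
82,Pyridine,110-86-1,5,,,0.0,0.0,0.0,1.5,0.0,0.8
83,Triethanolamine,102-71-6,5,,,0.0,6.0,3.0,0.0,3.1,1.6
84,Diethanolamine,111-42-2,5,,,0.3,0.0,0.1,5.9,2.2,4.1
85,Hydrocortisone,50-23-7,5,,,3.0,1.4,2.2,39.1,82.9,61.0
86,Isopropanol,67-63-0,5,,,1.4,6.5,4.0,0.0,0.5,0.3
87,Propylene glycol,57-55-6,5,,,1.0,0.0,0.5,0.0,0.6,0.3
88,"α-Methyl-1,3-benzodioxole-5-propionaldehyde",1205-17-0,5,,,50.6,28.4,39.5,44.9,3.7,24.3
89,Vanillin,121-33-5,5,,,9.3,4.0,6.7,3.2,0.0,1.6
90,Methyl salicylate,119-36-8,5,,,11.0,6.0,8.5,0.3,1.6,1.0
91,Benzaldehyde,100-52-7,5,,,9.3,0.0,4.7,7.2,0.0,3.6
92,Phenoxyethanol,122-99-6,5,,,12.3,4.0,8.2,11.4,25.4,18.4
93,4-Aminobenzoic acid,150-13-0,5,,,9.7,0.0,4.9,10.7,0.4,5.6
94,1-Butanol,71-36-3,6,,,0.0,0.0,0.0,0.0,1.2,0.6
95,Diethyl phthalate,84-66-2,6,,,4.7,0.0,2.3,0.8,0.0,0.4
96,Dimethylsulfoxide,67-68-5,6,,,0.3,0.0,0.1,0.4,1.2,0.8
97,Glycerol,56-81-5,6,,,5.0,14.0,9.5,0.0,2.1,1.0
98,Hexane,110-54-3,6,,,5.3,0.0,2.7,0.0,0.0,0.0
99,Lactic acid,50-21-5,6,,,0.2,0.0,0.1,0.0,0.8,0.4
100,Salicylic acid,69-72-7,6,,,0.8,5.0,2.9,3.5,21.1,12.3
101,Sodium lauryl sulfate,151-21-3,6,,,0.0,16.3,8.1,0.0,0.0,0.0
102,Tocopherol,59-02-9,6,,,0.0,85.0,42.5,0.0,7.1,3.6
103,Xylene,1330-20-7,6,,,0.8,0.0,0.4,9.7,0.0,4.9
104,Phenol,108-95-2,6,,,13.7,9.7,11.7,15.4,0.0,7.7
105,Tween 80,9005-65-6,6,,,18.5,0.0,9.3,49.1,12.9,31.0
106,Octanoic acid,124-07-2,6,,,13.0,22.7,17.8,0.0,0.9,0.5
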