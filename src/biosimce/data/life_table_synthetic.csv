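age,sex,annual_qx
0,female,0.00020997795154342747
1,female,0.00021108482456644317
2,female,0.00021231423874090716
3,female,0.0002136797603369267
4,female,0.00021519645747614113
5,female,0.00021688106638428906
6,female,0.00021875217604550024
7,female,0.0002208304332946831
8,female,0.000223138770608311
9,female,0.0002257026591074851
10,female,0.00022855038956015594
11,female,0.00023171338448135792
12,female,0.00023522654477070581
13,female,0.00023912863470920698
14,female,0.0002434627095538877
15,female,0.00024827659044612815
16,female,0.00025362339185963645
17,female,0.0002595621074017451
18,female,0.0002661582604145396
19,female,0.0002734846265387558
20,female,0.0002816220361931965
21,female,0.00029066026579638304
22,female,0.00030069902753249167
23,female,0.00031184906854331285
24,female,0.0003242333916250173
25,female,0.0003379886108366703
26,female,0.0003532664569048105
27,female,0.0003702354489388826
28,female,0.0003890827507895267
29,female,0.00041001623238989815
30,female,0.0004332667586476324
31,female,0.00045909073092598174
32,female,0.000487772908888906
33,female,0.0005196295435125897
34,female,0.0005550118554245032
35,female,0.0005943098964433791
36,female,0.0006379568363047428
37,female,0.0006864337210987781
38,female,0.000740274754976511
39,female,0.0008000731622260782
40,female,0.0008664876929539433
41,female,0.0009402498423677352
42,female,0.0010221718611116426
43,female,0.001113155642321506
44,female,0.0012142025801040734
45,female,0.001326424504078827
46,female,0.0014510558055328415
47,female,0.0015894668826917924
48,female,0.0017431790457040908
49,female,0.0019138810362299141
50,female,0.00210344733211687
51,female,0.00231395842459714
52,female,0.0025477232738241318
53,female,0.002807304168440772
54,female,0.0030955442362704533
55,female,0.0034155978761667427
56,female,0.0037709644055201608
57,female,0.004165525243850388
58,female,0.004603584980173325
59,female,0.005089916700238395
60,female,0.005629811978967614
61,female,0.00622913597308794
62,female,0.006894388078419245
63,female,0.007632768644794896
64,female,0.008452252268083327
65,female,0.009361668201897877
66,female,0.01037078844955408
67,female,0.011490424107439279
68,female,0.012732530531330832
69,female,0.014110321883803234
70,female,0.015638395589239074
71,female,0.017332867167608956
72,female,0.019211515832335713
73,female,0.02129394111292826
74,female,0.023601730589570602
75,female,0.02615863859234302
76,female,0.028990775407635616
77,female,0.03212680613125252
78,female,0.03559815779124653
79,female,0.03943923270978966
80,female,0.043687625254832496
81,female,0.04838433811759668
82,female,0.05357399300605814
83,female,0.05930502912923863
84,female,0.06562988102172673
85,female,0.0726051250811326
86,female,0.08029158162388961
87,female,0.08875435627369388
88,female,0.09806280106063692
89,female,0.10829037172655742
90,female,0.11951435343369288
91,female,0.1318154224362278
92,female,0.14527700644082375
93,female,0.15998440158639715
94,female,0.17602359956985025
95,female,0.19347977494380308
96,female,0.2124353807206173
97,female,0.23296780107577086
98,female,0.25514651436630287
99,female,0.2790297293746975
100,female,0.30466047445443734
0,male,0.0003249471932208481
1,male,0.00032757560834251187
2,male,0.0003304804482563428
3,male,0.0003336907830315816
4,male,0.00033723873966928775
5,male,0.00034115982351567986
6,male,0.0003454932734585636
7,male,0.0003502824544577843
8,male,0.0003555752913287913
9,male,0.00036142474811295955
10,male,0.0003678893578200615
11,male,0.00037503380783232565
12,male,0.0003829295868118532
13,male,0.00039165569956522983
14,male,0.00040129945699562963
15,male,0.0004119573490183326
16,male,0.0004237360091381426
17,male,0.00043675328029946225
18,male,0.00045113939261787195
19,male,0.0004670382647171678
20,male,0.0004846089416101762
21,male,0.0005040271834156895
22,male,0.0005254872206884587
23,male,0.0005492036937811973
24,male,0.000575413795463886
25,male,0.000604379638022623
26,male,0.0006363908682540664
27,male,0.0006717675561962455
28,male,0.0007108633860972713
29,male,0.00075406918106391
30,male,0.0008018167960570644
31,male,0.0008545834174561451
32,male,0.0009128963113199662
33,male,0.000977338066758704
34,male,0.0010485523855486845
35,male,0.0011272504742840805
36,male,0.0012142181010319497
37,male,0.0013103233846589735
38,male,0.001416525391791712
39,male,0.001533883623793697
40,male,0.0016635684842406517
41,male,0.0018068728262073952
42,male,0.0019652246882805313
43,male,0.0021402013386473406
44,male,0.002333544757909478
45,male,0.0025471787034940796
46,male,0.0027832275116992378
47,male,0.0030440368075649316
48,male,0.0033321963078969397
49,male,0.0036505649189110256
50,male,0.004002298347053679
51,male,0.004390879459569064
52,male,0.004820151650191784
53,male,0.00529435548483026
54,male,0.0058181689220355715
55,male,0.006396751423148661
56,male,0.007035792286873677
57,male,0.00774156356213429
58,male,0.008520977910737693
59,male,0.009381651806745106
60,male,0.010331974471406657
61,male,0.011381182949677049
62,male,0.012539443734943423
63,male,0.013817941340494633
64,male,0.015228974196779044
65,male,0.016786058219341315
66,male,0.018504038339509865
67,male,0.0203992082135529
68,male,0.022489438220290703
69,male,0.024794311714999462
70,male,0.02733526932052166
71,male,0.03013576079487912
72,male,0.03322140370674853
73,male,0.036620147762345456
74,male,0.04036244314394377
75,male,0.04448141062361344
76,male,0.04901301048575624
77,male,0.05399620640650127
78,male,0.05947311937305366
79,male,0.06548916545651351
80,male,0.07209316975217706
81,male,0.07933744704794332
82,male,0.08727783775397979
83,male,0.09597368531206807
84,male,0.10548773869955996
85,male,0.115885960766972
86,male,0.12723722004235694
87,male,0.13961284037867183
88,male,0.15308597954113834
89,male,0.16773080472460689
90,male,0.1836214303354181
91,male,0.2008305815535445
92,male,0.21942794672278032
93,male,0.23947818316375014
94,male,0.26103854539840365
95,male,0.28415611302203814
96,male,0.30886460872992094
97,male,0.3351808165931355
98,male,0.36310063791292235
99,male,0.3925948580853281
100,male,0.42360474376020196
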