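id,subtype,sex,age,edu,onset,lesion_volume
1,Broca,m,85,10,46,11393
2,Broca,m,54,13,35,18632
3,Global,m,79,11,64,23860
4,Global,m,72,11,42,27054
5,Mixed nonfluent,m,67,11,44,31317
6,Global,m,72,11,155,32981
7,Global,m,58,13,57,33239
8,Global,m,52,11,73,37822
9,Mixed nonfluent,m,68,12,50,41379
10,Conduction,m,67,17,14,6557
11,Global,m,74,11,18,19500
12,Mixed nonfluent,m,58,13,32,14625
13,Global,m,66,11,12,14890
14,Broca,m,62,11,104,27242
15,Mixed nonfluent,m,64,11,29,33239
16,Conduction,m,67,11,13,4879
17,Mixed nonfluent,f,75,11,160,12057
18,Mixed nonfluent,m,63,12,42,31599
19,Conduction,m,68,11,37,4773
20,Mixed nonfluent,m,78,13,36,34242
21,Conduction,f,77,16,34,6843
22,TSA,m,63,12,24,5822
23,Broca,m,61,11,16,3528
24,Conduction,f,46,16,21,3897
25,Broca,m,51,12,34,20043
26,Mixed nonfluent,m,79,11,63,33678
27,Mixed nonfluent,f,52,11,99,40313
28,Broca,m,59,13,37,13080
29,Mixed nonfluent,m,81,11,69,28144
30,Broca,m,50,12,16,26218
31,Anomia,f,53,11,47,1526
32,Broca,m,82,10,13,12131
33,Mixed nonfluent,m,73,11,23,22732
34,TMA,f,73,11,46,23863
35,Anomia,m,51,13,72,22948
36,Broca,f,48,12,16,5273
37,Anomia,f,69,19,39,9159
38,Mixed nonfluent,m,76,11,192,42568
39,Anomia,f,51,11,66,6975
40,Broca,f,77,11,56,13577
41,Mixed nonfluent,m,73,11,114,36877
42,Broca,m,80,12,65,18163
43,Anomia,m,65,10,85,6607
44,Anomia,m,44,11,40,8437
45,Anomia,m,86,9,17,8528
46,Anomia,m,59,11,34,16433
47,Anomia,f,44,13,37,18948
48,Anomia,m,68,11,21,3311
49,Anomia,m,75,11,11,1481
50,Anomia,m,87,12,35,8238
51,Anomia,m,66,11,126,15492
52,Mixed nonfluent,m,67,11,120,26097
53,Conduction,m,84,9,35,7854
54,Anomia,m,85,10,69,21489
55,Mixed nonfluent,f,67,14,176,26283
56,Anomia,m,65,17,25,4806
57,Anomia,m,68,11,14,8788
58,Anomia,m,52,17,33,11915
59,TMA,m,76,11,116,11239
60,Anomia,m,45,11,25,10409
61,Anomia,m,50,19,16,4538
62,Anomia,f,58,11,278,12699
63,Anomia,m,67,11,60,10073
64,Broca,m,58,11,135,18392
65,Anomia,m,56,16,17,6974
66,Anomia,f,73,11,89,8921
67,Anomia,f,68,16,22,8118
68,Anomia,f,52,12,76,9767
69,Anomia,f,43,16,15,175
70,Anomia,m,63,12,10,18639
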