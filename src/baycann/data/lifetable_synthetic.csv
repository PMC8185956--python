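age,mu
50,0.00350527
51,0.00381625
52,0.00415481
53,0.00452342
54,0.00492472
55,0.00536163
56,0.00583730
57,0.00635516
58,0.00691898
59,0.00753281
60,0.00820110
61,0.00892867
62,0.00972080
63,0.01058320
64,0.01152211
65,0.01254432
66,0.01365721
67,0.01486884
68,0.01618796
69,0.01762411
70,0.01918767
71,0.02088994
72,0.02274323
73,0.02476095
74,0.02695767
75,0.02934927
76,0.03195305
77,0.03478783
78,0.03787411
79,0.04123419
80,0.04489236
81,0.04887508
82,0.05321114
83,0.05793187
84,0.06307142
85,0.06866693
86,0.07475886
87,0.08139125
88,0.08861204
89,0.09647344
90,0.10503228
91,0.11435044
92,0.12449527
93,0.13554013
94,0.14756485
95,0.16065637
96,0.17490933
97,0.19042677
98,0.20732088
99,0.22571378
100,0.24573844
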