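variable,stratum,Overall,TNF-α-targeted inhibitors,conventional DMARDs,PDE4-targeted inhibitor,B-cell inhibitors,interleukin inhibitors,JAK inhibitors,T-cell inhibitors
total,all,4869,1989,1339,19,589,405,259,269
age,<=45,314,97,118,1,24,43,11,20
age,45-65,1368,554,466,6,92,98,69,83
age,>65,1471,599,447,5,112,112,106,90
age,Unknown,1716,739,308,7,361,152,73,76
sex,Female,2864,1236,777,10,174,269,183,215
sex,Male,1531,639,480,7,167,118,70,50
sex,Unknown,474,114,82,2,248,18,6,4
country,Canada,1624,307,619,2,323,183,46,144
country,United States,1083,645,177,10,44,67,103,37
country,United Kingdom,461,211,125,0,75,27,2,21
country,Germany,242,94,84,0,33,14,6,11
country,Argentina,146,85,3,0,0,2,47,9
country,France,133,35,56,2,22,13,3,2
country,Brazil,123,86,1,0,13,12,0,11
country,China,75,25,14,0,17,5,11,3
country,Japan,62,19,31,0,1,5,5,1
country,Denmark,58,20,30,0,7,1,0,0
country,Sweden,58,30,10,4,8,3,1,2
country,Others,402,171,97,1,40,52,14,27
country,Unknown,402,261,92,0,6,21,21,1
reporter,Health-professional,3190,1117,1026,17,487,286,90,167
reporter,Consumer,1513,784,242,2,96,119,168,102
reporter,Unknown,166,88,71,0,6,0,1,0
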