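marker,species,chromosome,dye,known_allele_range
18-3,mouse,18,6FAM,13-28
4-2,mouse,4,6FAM,13-23.3
11-1,mouse,11,6FAM,17-23.3
6-7,mouse,6,6FAM,11-26
19-2,mouse,19,6FAM,10-16
1-2,mouse,1,VIC,12-30.1
7-1,mouse,7,VIC,19.2-33.2
1-1,mouse,1,VIC,10-19
3-2,mouse,3,VIC,9-25
8-1,mouse,8,VIC,6-19
2-1,mouse,2,NED,8-17.1
15-3,mouse,15,NED,12-31.3
6-4,mouse,6,NED,12.2-21
11-2,mouse,11,NED,12-26.2
17-2,mouse,17,PET,11-22
12-1,mouse,12,PET,15-24.1
5-5,mouse,5,PET,11-22
X-1,mouse,X,PET,15.2-37
13-1,mouse,13,PET,11-20.1
D8S1106,human,8,VIC,
D4S2408,human,4,NED,
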