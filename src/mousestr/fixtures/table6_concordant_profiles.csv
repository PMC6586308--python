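marker,NCTC clone 929,BALB/3T3 clone A31,L1210,CMT-93,STO,NMuMG,P19,M-NFS-60,Hepa-1c1c7,M-1,JC,WEHI-13VAR,RAW 264.7 gamma NO-,EOC 20,EMT6,YAC-1,M1,BCL1 clone 5B1b,2E8,J558,RAW 264.7
18-3,16,18,16;17,16,19,18,16;17,17,16;17,17,18;19,17;18,18,16,18;19,18,18,18;19,18,18,18
4-2,20.3,21.3,20.3,20.3,20.3,20.3,13;21.3,19.3;20.3,18.3;19.3,20.3,21.3,21.3;22.3,22.3;23.3,19.3,21.3,21.3,20.3,21.3,21.3,21.3,22.3
6-7,12,12,12,15,12,15,12,12,15,12,12,12,12,12,12,12,16,12,12,12,12
19-2,12,14,12,14,12,12,12;14,11;12,10;11,13,14,13,12;14,12,13,12;13,13;14,12;13,14,14,14
1-2,17,17,16,19;20,16,17,16;17,17,13,19,17;18,17,17,16,17;18,17;18,13,17,17,17,17
7-1,25;26;27,25.2,27;28,26.2,25.2,25.2,26,28;29,25.2,26.2,24.2,25.2,25.2,26,25.2,25.2,25.2,26.2,24.2,25.2,25.2
1-1,10,16,15;17,15,12,15;16,10,10;16,14;15,17,14,15,15;16,10,15,11,16,14,15,16,15;16
3-2,13;14,14,13,14,14,14,14,13;14,10,14,14,14,14,14,14,14,12,14,14,14,14
8-1,16,13,16,16,16,16,16,15;16,15,16,13,13,13,16;17,13,16,16;17,13,13,13,13
2-1,9,16,15,16,9,15;16,9,9;16,14,9;16,16,16;17,16,9,16,16,9,15,16,16,16
15-3,24.3;25.3;26.3,22.3,21.3;22.3,22.3,20.3,21.3;22.3,26.3,20.3;21.3,17;18;19,22.3,22.3;23.3,22.3,22.3,25.3,22.3;23.3,22.3,22.3,22.3,23.3;24.3,22.3,22.3
6-4,17;18,18,17,18;19,15.3,17;18,18,15.3;18,18;19,15,18,18;19,18,19,18,18,16.3,18,17,18,18
11-2,15;16,17,17,16,15,15,16,17;19,16,16,17,17;18,17,17,18,15,15;16,18,16;17,17,17
17-2,15,15;16,16,15;16,13,16;17,15,13;15,14,15,16,16,14;16,16,16,16,12,15,17,16,14;16
12-1,16,16,16,17,19,16,16,16;20,17;18,17,16,16,16;17,16,16,16,16;17,16,16,16,16
5-5,14,14,13,14;16;17,14,15,14,14;15,17;18,17,14,13;14,14,15,13;15,16,14,13;14,14,14,14
X-1,26;27,25,27,27,26,27;28,26,25;27,25,28,25,26,25,27,24,26,26,24;25,26,25,24
13-1,17,16.2,17,17,16.2,16.2;17,17,13;15.2,17.1,17,16.2,15.2,16.2,17,16.2,16.2;17.2,16.2,16.2,16.2,16.2,16.2
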