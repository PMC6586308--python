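marker,C1
18-3,16;19;21
4-2,16.3;19.3;20.3
11-1,19.3;20.3
6-7,12;15;16
19-2,12;13;14
1-2,13;15;18
7-1,26.2;28;29
1-1,11;14
3-2,13.1;14
8-1,14;15;16
2-1,9
15-3,20.3;22.3;23.3
6-4,15.3;18;18.3
11-2,15;15.3;18
17-2,15;16
12-1,15;16;18
5-5,13;16;17
X-1,24;25;28
13-1,16.2;17;18
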