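marker,known_allele_range,stutter_ratio_pct,represented_allele_range
18-3,13-28,20.52,16-23
4-2,13-23.3,13.80,16.3-22.3
11-1,17-23.3,19.75,17.3-23.3
6-7,11-26,16.13,12-26
19-2,10-16,11.77,10-16
1-2,12-30.1,13.20,13-22
7-1,19.2-33.2,12.98,24.2-33.2
1-1,10-19,13.71,10-20
3-2,9-25,16.07,9-25
8-1,6-19,18.12,6-18.3
2-1,8-17.1,17.71,9-16
15-3,12-31.3,19.03,18.3-27.3
6-4,12.2-21,12.16,15.3-21
11-2,12-26.2,17.16,15-26.2
17-2,11-22,16.98,12-22
12-1,15-24.1,11.90,15-23
5-5,11-22,13.72,11-21
X-1,15.2-37,18.74,21-37
13-1,11-20.1,22.60,11-20.1
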