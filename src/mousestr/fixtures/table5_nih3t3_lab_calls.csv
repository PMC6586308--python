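cell_line,lab_id,marker,alleles
NIH/3T3,1,18-3,17;19
NIH/3T3,1,4-2,19.3;20.3
NIH/3T3,1,6-7,12
NIH/3T3,1,19-2,11;12
NIH/3T3,1,1-2,13;17
NIH/3T3,1,7-1,29
NIH/3T3,1,1-1,10
NIH/3T3,1,3-2,14;15
NIH/3T3,1,8-1,15
NIH/3T3,1,2-1,9
NIH/3T3,1,15-3,20.3
NIH/3T3,1,6-4,15.3
NIH/3T3,1,11-2,15;17
NIH/3T3,1,17-2,13;14
NIH/3T3,1,12-1,20
NIH/3T3,1,5-5,14;15
NIH/3T3,1,X-1,25
NIH/3T3,1,13-1,16.2
NIH/3T3,2,18-3,17;19
NIH/3T3,2,4-2,19.3;20.3
NIH/3T3,2,6-7,12
NIH/3T3,2,19-2,11;12
NIH/3T3,2,1-2,13;17
NIH/3T3,2,7-1,29
NIH/3T3,2,1-1,10
NIH/3T3,2,3-2,14;15
NIH/3T3,2,8-1,15
NIH/3T3,2,2-1,9
NIH/3T3,2,15-3,20.3
NIH/3T3,2,6-4,15.3
NIH/3T3,2,11-2,15;17
NIH/3T3,2,17-2,13;14
NIH/3T3,2,12-1,20
NIH/3T3,2,5-5,14;15
NIH/3T3,2,X-1,25
NIH/3T3,2,13-1,16.2
NIH/3T3,3,18-3,17;19
NIH/3T3,3,4-2,19.3;20.3
NIH/3T3,3,6-7,12
NIH/3T3,3,19-2,11;12
NIH/3T3,3,1-2,13;17
NIH/3T3,3,7-1,29
NIH/3T3,3,1-1,10
NIH/3T3,3,3-2,14;15
NIH/3T3,3,8-1,15
NIH/3T3,3,2-1,9
NIH/3T3,3,15-3,20.3
NIH/3T3,3,6-4,15.3
NIH/3T3,3,11-2,15;17
NIH/3T3,3,17-2,13;14
NIH/3T3,3,12-1,20
NIH/3T3,3,5-5,14;15
NIH/3T3,3,X-1,25
NIH/3T3,3,13-1,16.2
NIH/3T3,4,18-3,17;19
NIH/3T3,4,4-2,19.3
NIH/3T3,4,6-7,12
NIH/3T3,4,19-2,11;12
NIH/3T3,4,1-2,13;17
NIH/3T3,4,7-1,29
NIH/3T3,4,1-1,10
NIH/3T3,4,3-2,14;15
NIH/3T3,4,8-1,15
NIH/3T3,4,2-1,9
NIH/3T3,4,15-3,20.3
NIH/3T3,4,6-4,15.3
NIH/3T3,4,11-2,15;17
NIH/3T3,4,17-2,13;14
NIH/3T3,4,12-1,20
NIH/3T3,4,5-5,14;15
NIH/3T3,4,X-1,25
NIH/3T3,4,13-1,16.2
NIH/3T3,5,18-3,17;19
NIH/3T3,5,4-2,19.3;20.3
NIH/3T3,5,6-7,12
NIH/3T3,5,19-2,11;12
NIH/3T3,5,1-2,13;17
NIH/3T3,5,7-1,29
NIH/3T3,5,1-1,10
NIH/3T3,5,3-2,14;15
NIH/3T3,5,8-1,15
NIH/3T3,5,2-1,9
NIH/3T3,5,15-3,20.3
NIH/3T3,5,6-4,15.3
NIH/3T3,5,11-2,15;17
NIH/3T3,5,17-2,13;14
NIH/3T3,5,12-1,20
NIH/3T3,5,5-5,14;15
NIH/3T3,5,X-1,25
NIH/3T3,5,13-1,16.2
NIH/3T3,6,18-3,17;19
NIH/3T3,6,4-2,19.3;20.3
NIH/3T3,6,6-7,12
NIH/3T3,6,19-2,11;12
NIH/3T3,6,1-2,13;17
NIH/3T3,6,7-1,29
NIH/3T3,6,1-1,10
NIH/3T3,6,3-2,14;15
NIH/3T3,6,8-1,15
NIH/3T3,6,2-1,9
NIH/3T3,6,15-3,20.3
NIH/3T3,6,6-4,15.3
NIH/3T3,6,11-2,15;17
NIH/3T3,6,17-2,13;14
NIH/3T3,6,12-1,20
NIH/3T3,6,5-5,14;15
NIH/3T3,6,X-1,25
NIH/3T3,6,13-1,16.2
NIH/3T3,7,18-3,17;19
NIH/3T3,7,4-2,19.3;20.3
NIH/3T3,7,6-7,12
NIH/3T3,7,19-2,11;12
NIH/3T3,7,1-2,13;17
NIH/3T3,7,7-1,29
NIH/3T3,7,1-1,10
NIH/3T3,7,3-2,14;15
NIH/3T3,7,8-1,15
NIH/3T3,7,2-1,9
NIH/3T3,7,15-3,20.3
NIH/3T3,7,6-4,15.3
NIH/3T3,7,11-2,15;17
NIH/3T3,7,17-2,13;14
NIH/3T3,7,12-1,20
NIH/3T3,7,5-5,14;15
NIH/3T3,7,X-1,25
NIH/3T3,7,13-1,16.2
NIH/3T3,8,18-3,17;19
NIH/3T3,8,4-2,19.3;20.3
NIH/3T3,8,6-7,12
NIH/3T3,8,19-2,11;12
NIH/3T3,8,1-2,13;17
NIH/3T3,8,7-1,29
NIH/3T3,8,1-1,10
NIH/3T3,8,3-2,14;15
NIH/3T3,8,8-1,15
NIH/3T3,8,2-1,9
NIH/3T3,8,15-3,20.3
NIH/3T3,8,6-4,15.3
NIH/3T3,8,11-2,15;17
NIH/3T3,8,17-2,13;14
NIH/3T3,8,12-1,20
NIH/3T3,8,5-5,14;15
NIH/3T3,8,X-1,25
NIH/3T3,8,13-1,16.2
NIH/3T3,9,18-3,17;19
NIH/3T3,9,4-2,19.3;20.3
NIH/3T3,9,6-7,12
NIH/3T3,9,19-2,11;12
NIH/3T3,9,1-2,13;17
NIH/3T3,9,7-1,29
NIH/3T3,9,1-1,10
NIH/3T3,9,3-2,14;15
NIH/3T3,9,8-1,15
NIH/3T3,9,2-1,9
NIH/3T3,9,15-3,20.3
NIH/3T3,9,6-4,15.3
NIH/3T3,9,11-2,15;17
NIH/3T3,9,17-2,13;14
NIH/3T3,9,12-1,20
NIH/3T3,9,5-5,14;15
NIH/3T3,9,X-1,25
NIH/3T3,9,13-1,16.2
NIH/3T3,10,18-3,17;19
NIH/3T3,10,4-2,19.3;20.3
NIH/3T3,10,6-7,12
NIH/3T3,10,19-2,11;12
NIH/3T3,10,1-2,13;17
NIH/3T3,10,7-1,29
NIH/3T3,10,1-1,10
NIH/3T3,10,3-2,14;15
NIH/3T3,10,8-1,15
NIH/3T3,10,2-1,9
NIH/3T3,10,15-3,20.3
NIH/3T3,10,6-4,15.3
NIH/3T3,10,11-2,15;17
NIH/3T3,10,17-2,13;14
NIH/3T3,10,12-1,20
NIH/3T3,10,5-5,14;15
NIH/3T3,10,X-1,25
NIH/3T3,10,13-1,16.2
NIH/3T3,11,18-3,17;19
NIH/3T3,11,4-2,19.3;20.3
NIH/3T3,11,6-7,12
NIH/3T3,11,19-2,11;12
NIH/3T3,11,1-2,13;17
NIH/3T3,11,7-1,29
NIH/3T3,11,1-1,10
NIH/3T3,11,3-2,14;15
NIH/3T3,11,8-1,15
NIH/3T3,11,2-1,9
NIH/3T3,11,15-3,20.3
NIH/3T3,11,6-4,15.3
NIH/3T3,11,11-2,15;17
NIH/3T3,11,17-2,13;14
NIH/3T3,11,12-1,20
NIH/3T3,11,5-5,14;15
NIH/3T3,11,X-1,25
NIH/3T3,11,13-1,16.2
NIH/3T3,12,18-3,17;19
NIH/3T3,12,4-2,19.3;20.3
NIH/3T3,12,6-7,12
NIH/3T3,12,19-2,11;12
NIH/3T3,12,1-2,13;17
NIH/3T3,12,7-1,29
NIH/3T3,12,1-1,10
NIH/3T3,12,3-2,14;15
NIH/3T3,12,8-1,15
NIH/3T3,12,2-1,9
NIH/3T3,12,15-3,20.3
NIH/3T3,12,6-4,15.3
NIH/3T3,12,11-2,15;17
NIH/3T3,12,17-2,13;14
NIH/3T3,12,12-1,20
NIH/3T3,12,5-5,14;15
NIH/3T3,12,X-1,25
NIH/3T3,12,13-1,16.2
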