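parental,derivative,percent_match
NCTC clone 929,A9,85
WEHI 164,WEHI-13VAR,91
CT26.WT,CT26.CL25,87
B16-F0,B16-F1,94
RAW 264.7,RAW 264.7 gamma NO-,95
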