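source,destination,rate_per_day,provenance
ETseq,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day); applies to all particle-bearing respiratory compartments except ET1"
ET2prime,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
BBprime,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
BBseq,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
bbprime,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
bbseq,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
ALV,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
INT,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
LNET,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
LNTH,Blood,30.0,"ICRP Publication 130 default Type F dissolution (fr = 1, sr = 30 per day)"
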