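region,component,c,provenance
ET1,ae,3.3124,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.82"
ET2,ae,3.3124,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.82"
BB,ae,2.4964,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.58"
bb,ae,2.4964,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.58"
AI,ae,1.69,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.30"
ET1,th,1.3924,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.18"
ET2,th,1.3924,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.18"
BB,th,1.5129,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.23"
bb,th,1.5129,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.23"
AI,th,1.5129,"ICRP 66 Table 14 scaling constant; multiplier GSD = sqrt(c) = 1.23"
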