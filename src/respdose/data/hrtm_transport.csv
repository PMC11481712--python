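source,destination,rate_per_day,provenance
ET1,Environment,0.6,"ICRP Publication 130, fig 3.4 (particle transport from anterior nose to environment)"
ET1,ET2prime,1.5,"ICRP Publication 130, fig 3.4 (anterior to posterior extrathoracic airways)"
ET2prime,Oesophagus,100.0,"ICRP Publication 130, fig 3.4 (extrathoracic clearance to oesophagus)"
ETseq,LNET,0.001,"ICRP Publication 130, fig 3.4 (sequestered extrathoracic deposit to extrathoracic lymph nodes)"
BBprime,ET2prime,10.0,"ICRP Publication 130, fig 3.4 (bronchial mucociliary clearance)"
BBseq,LNTH,0.001,"ICRP Publication 130, fig 3.4 (sequestered bronchial deposit to thoracic lymph nodes)"
bbprime,BBprime,0.2,"ICRP Publication 130, fig 3.4 (bronchiolar mucociliary clearance)"
bbseq,LNTH,0.001,"ICRP Publication 130, fig 3.4 (sequestered bronchiolar deposit to thoracic lymph nodes)"
ALV,bbprime,0.002,"ICRP Publication 130, fig 3.4 (alveolar clearance to bronchioles; reference value, median of the sampled distribution)"
ALV,INT,0.001,"ICRP Publication 130, fig 3.4 (alveolar penetration to interstitium; reference value, median of the sampled distribution)"
INT,LNTH,0.00003,"ICRP Publication 130, fig 3.4 (interstitium to thoracic lymph nodes; reference value, median of the sampled distribution)"
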