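source,destination,rate_per_day,provenance
Oesophagus,Gut,720.0,"Oesophageal transit (~2 min) into the lumped gut compartment; as adopted in this package"
Gut,Blood,594.0,"Iodine fractional gut absorption fA = 0.99 via competing small-intestine rates 6*fA/(1-fA) per day; ICRP alimentary-tract convention, as adopted in this package"
Gut,Excreta,6.0,"Small-intestine onward transit 6 per day toward faecal excretion; ICRP alimentary-tract convention"
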