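nuclide,half_life_days,provenance
I-131,8.0252,"Physical half-life of iodine-131 (8.0252 d); decay constant stored as ln2 / half-life"
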