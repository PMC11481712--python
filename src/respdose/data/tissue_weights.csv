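tissue,w_T,provenance
RedMarrow,0.12,"ICRP effective-dose tissue weighting factors"
Colon,0.12,"ICRP effective-dose tissue weighting factors"
Lung,0.12,"ICRP effective-dose tissue weighting factors"
Stomach,0.12,"ICRP effective-dose tissue weighting factors"
Breast,0.12,"ICRP effective-dose tissue weighting factors"
Remainder,0.12,"ICRP effective-dose tissue weighting factors (remainder tissues treated as a single pseudo-tissue)"
Gonads,0.08,"ICRP effective-dose tissue weighting factors"
Bladder,0.04,"ICRP effective-dose tissue weighting factors"
Oesophagus,0.04,"ICRP effective-dose tissue weighting factors"
Liver,0.04,"ICRP effective-dose tissue weighting factors"
Thyroid,0.04,"ICRP effective-dose tissue weighting factors"
BoneSurface,0.01,"ICRP effective-dose tissue weighting factors"
Brain,0.01,"ICRP effective-dose tissue weighting factors"
SalivaryGlands,0.01,"ICRP effective-dose tissue weighting factors"
Skin,0.01,"ICRP effective-dose tissue weighting factors"
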