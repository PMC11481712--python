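compartment,source_region,provenance
ET1,ET1,"Anterior nose surface source"
ETseq,ET2,"Sequestered extrathoracic deposit counted with the posterior extrathoracic source"
ET2prime,ET2,"Posterior extrathoracic airways source"
BBprime,BB,"Bronchial source region"
BBseq,BB,"Bronchial source region (sequestered)"
bbprime,bb,"Bronchiolar source region"
bbseq,bb,"Bronchiolar source region (sequestered)"
ALV,AI,"Alveolar-interstitial source region"
INT,AI,"Alveolar-interstitial source region (interstitium)"
LNET,LNET,"Extrathoracic lymph-node source"
LNTH,LNTH,"Thoracic lymph-node source"
Oesophagus,Oesophagus-c,"Oesophagus contents source"
Gut,Gut-c,"Lumped gut contents source"
Blood,Blood,"Circulating iodide source"
BloodOrganic,Blood,"Circulating organic iodine counted with the blood source"
Thyroid1,Thyroid,"Thyroid source (trapped iodide)"
Thyroid2,Thyroid,"Thyroid source (organic iodine)"
SalivaryGlands,SalivaryGlands,"Salivary gland source"
StomachWall,StomachWall,"Stomach wall source"
Other,Other,"Extrathyroidal tissue source"
UBladder,UBladder-c,"Urinary bladder contents source"
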