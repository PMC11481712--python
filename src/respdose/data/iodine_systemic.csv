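source,destination,rate_per_day,provenance
Blood,Thyroid1,7.26,"ICRP Publication 137, fig 5.2 (iodide uptake from blood into the thyroid trapping compartment; physiological iodine model)"
Blood,UBladder,11.84,"ICRP Publication 137, fig 5.2 (renal clearance of blood iodide to urinary bladder contents)"
Blood,SalivaryGlands,5.16,"ICRP Publication 137, fig 5.2 (secretion of blood iodide into salivary glands)"
Blood,StomachWall,8.60,"ICRP Publication 137, fig 5.2 (secretion of blood iodide into stomach wall)"
Thyroid1,Blood,36.0,"ICRP Publication 137, fig 5.2 (leak of trapped thyroid iodide back to blood); as adopted in this package"
Thyroid1,Thyroid2,95.0,"ICRP Publication 137, fig 5.2 (organification of trapped iodide within the thyroid); as adopted in this package"
Thyroid2,BloodOrganic,0.0077,"ICRP Publication 137, fig 5.2 (secretion of organic iodine, ~90 d biological half-time); as adopted in this package"
BloodOrganic,Other,15.0,"ICRP Publication 137, fig 5.2 (distribution of circulating organic iodine to extrathyroidal tissue); as adopted in this package"
Other,Blood,1.32,"ICRP Publication 137, fig 5.2 (deiodination of extrathyroidal organic iodine returning iodide to blood); as adopted in this package"
Other,Gut,0.11,"ICRP Publication 137, fig 5.2 (biliary/faecal path of organic iodine into gut contents); as adopted in this package"
SalivaryGlands,Gut,50.0,"ICRP Publication 137, fig 5.2 (salivary secretion into the alimentary tract); as adopted in this package"
StomachWall,Gut,50.0,"ICRP Publication 137, fig 5.2 (gastric secretion into the alimentary tract); as adopted in this package"
UBladder,Excreta,12.0,"ICRP urinary bladder voiding rate; as adopted in this package"
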