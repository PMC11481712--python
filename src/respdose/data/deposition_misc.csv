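name,value,provenance
dead_space_ET_cm3,50.0,"Extrathoracic anatomical dead space (cm^3), adult reference"
dead_space_BB_cm3,49.0,"Bronchial anatomical dead space (cm^3), adult reference"
dead_space_bb_cm3,47.0,"Bronchiolar anatomical dead space (cm^3), adult reference"
et1_retention_fraction,0.65,"ICRP Publication 130 extrathoracic redistribution: fraction of the anterior-nose filter deposit retained in ET1, remainder reassigned to ET2"
inhalability_a,7.6e-4,"ICRP 66 inhalability fit: eta_I = 1 - 0.5 * (1 - 1/(1 + a*d_ae^p))"
inhalability_p,2.8,"ICRP 66 inhalability fit exponent"
mean_free_path_um,0.0712,"Air mean free path (um) at airway conditions, used in the Cunningham slip correction"
air_viscosity_poise,1.89e-4,"Dynamic viscosity of air at 37 C (poise)"
air_temperature_K,310.0,"Airway air temperature (K)"
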