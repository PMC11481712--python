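activity,ventilation_m3_h,frequency_per_min,tidal_volume_L,fn,provenance
sitting,0.54,12.0,0.75,1.0,"ICRP 66 reference adult male, sitting awake"
light_exercise,1.5,20.0,1.25,1.0,"ICRP 66 reference adult male, light exercise"
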