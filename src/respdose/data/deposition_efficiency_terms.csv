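region,component,pathway,form,argument,a,p,provenance
ET1,ae,nose,saturating,impaction,3.0e-4,1.0,"ICRP 66 empirical nasal (anterior) inertial-impaction fit on d_ae^2*flow"
ET2,ae,nose,saturating,impaction,5.5e-5,1.17,"ICRP 66 empirical posterior extrathoracic inertial-impaction fit on d_ae^2*flow"
ET2,ae,mouth,saturating,impaction,1.1e-4,1.0,"Oral-path extrathoracic impaction fit of the same family (weaker than the nasal path); as adopted in this package"
BB,ae,any,exponential,impaction,4.08e-6,1.152,"Bronchial inertial-impaction term of the ICRP empirical family; as adopted in this package"
BB,ae,any,exponential,settling,0.006,1.0,"Bronchial gravitational-settling term (settling velocity * residence time / airway calibre); as adopted in this package"
bb,ae,any,exponential,impaction,1.0e-6,1.108,"Bronchiolar inertial-impaction term; as adopted in this package"
bb,ae,any,exponential,settling,0.03,1.0,"Bronchiolar gravitational-settling term; as adopted in this package"
AI,ae,any,exponential,settling,0.1,1.0,"Alveolar-interstitial gravitational-settling term (alveolar length scale ~0.03 cm); as adopted in this package"
ET1,th,nose,saturating,diffusion,4.4,1.0,"Nasal (anterior) diffusional-deposition fit on D*t; as adopted in this package"
ET2,th,nose,saturating,diffusion,2.2,1.0,"Posterior extrathoracic diffusional-deposition fit; as adopted in this package"
ET2,th,mouth,saturating,diffusion,2.2,1.0,"Oral-path extrathoracic diffusional-deposition fit; as adopted in this package"
BB,th,any,exponential,diffusion,0.5,0.66,"Bronchial diffusional-deposition term; as adopted in this package"
bb,th,any,exponential,diffusion,0.8,0.66,"Bronchiolar diffusional-deposition term; as adopted in this package"
AI,th,any,exponential,diffusion,0.6,0.66,"Alveolar-interstitial diffusional-deposition term; as adopted in this package"
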