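scenario,activity,air_fraction,provenance
worker,sitting,0.152542,"ICRP reference worker 8 h shift: one third sitting at 0.54 m3/h -> 1.44 m3 of 9.44 m3 breathed"
worker,light_exercise,0.847458,"ICRP reference worker 8 h shift: two thirds light exercise at 1.5 m3/h -> 8.00 m3 of 9.44 m3 breathed"
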