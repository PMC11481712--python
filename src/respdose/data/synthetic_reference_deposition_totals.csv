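amad_um,total_deposition_fraction,provenance
0.3,0.314478,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
0.5,0.375153,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
0.7,0.453684,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
1,0.556099,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
2,0.747038,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
3,0.817731,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
5,0.843799,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
7,0.825173,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
10,0.782719,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
15,0.719051,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
20,0.671907,"synthetic: frozen output of this package reference deposition model (reference worker, GSD 2.5); stand-in for the external ICRP reference table, used to exercise the benchmark harness offline"
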