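# Four virtual cell lines +/- mutations under a CpG pulse
recipe: mutation_response
seed: 1
outdir: results/mutation_response
population: {n_cells: 25, cv: 0.11}
stimulus: {kind: CpG_pulse, amplitude: 1.0, t_end: 8.0}
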