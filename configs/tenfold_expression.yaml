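# Baseline + 10-fold RelA/cRel/RelB populations under a TME step
recipe: tenfold_expression
seed: 1
outdir: results/tenfold_expression
population: {n_cells: 25, cv: 0.11}
stimulus: {kind: TME_step, amplitude: 1.0, t_end: 8.0}
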