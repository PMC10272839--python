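# Six population presets x 1000 cells -> pooled basal fingerprint
recipe: basal_fingerprints
seed: 1
outdir: results/basal_fingerprints
population: {n_cells: 1000, cv: 0.11}
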