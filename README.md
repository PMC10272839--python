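# nfkbfp — NF-κB fingerprinting for B-cell lymphoma

Diffuse large B-cell lymphoma (DLBCL) cells differ widely — between cell
lines, between subclones of a single line, and from healthy B cells — in
how much of each NF-κB transcription-factor subunit (RelA, RelB, cRel,
p50, p52) they contain, and those differences, together with recurrent
mutations in receptor-proximal signalling (MYD88 L265P, CD79B, TAK1),
decide how a tumour responds to stimuli from its microenvironment (TME),
such as TLR9 agonists. `nfkbfp` implements the two halves of that
analysis as a tested Python package:

* **NF-κB fingerprinting** — the flow-cytometry statistic: gate B cells,
  subtract each channel's isotype-control MFI per event, pool the cell
  populations to be compared, and z-standardise each marker over the pool
  (mean 0, SD 1), giving a per-cell RelA/RelB/cRel profile,

  z_i,m = (x_i,m − μ_m^pooled) / σ_m^pooled,

  that is comparable within and between populations; and
* **mechanistic simulation** — a multi-dimer NF-κB ODE model (canonical
  and non-canonical pathways, explicit dimer formation over a shared p50
  pool, IκBα/ε feedback, NEMO-IKK input) coupled to TLR9 and BCR receptor
  modules whose active-IKK outputs are summed into the core model's input.
  Heterogeneous single-cell populations are simulated by drawing each
  cell's expression and degradation parameters from a truncated normal
  with 11% coefficient of variation, running every cell to steady state
  at basal input and then through a stimulated time course. Virtual cell
  lines scale subunit expression by 10^z of a gene's expression z-score
  (z = 0 → ×1, z = 1 → ×10) or by calibration against a measured
  fingerprint, and carry their known mutations as parameter perturbations.

The package is organised as an analysis project: the library under
`src/nfkbfp/` (reaction networks, core model, receptor modules,
populations, cell lines, fingerprint statistics, synthetic-data
generators, config/CLI), narrative drivers under `analysis/`
(`01_…`–`05_…`), and YAML experiment recipes under `configs/`. Everything
runs on synthetic data generated by the package itself — no downloads.

## Worked example

The two-subclone analysis (`analysis/03_subclone_flow.py`) generates the
default synthetic U2932-like sample — 40,000 events in two subclones that
differ in CD20/CD38 and RelA — and runs the full pipeline:

```
$ python analysis/03_subclone_flow.py
gated 37668/40000 events
  RelA: R1/R2 corrected-MFI fold 2.20 (event-level p 0)
  cRel: R1/R2 corrected-MFI fold 1.00 (event-level p 0.75)
  RelB: R1/R2 corrected-MFI fold 1.00 (event-level p 0.45)
fingerprint median z by subclone:
    cRel  RelA  RelB
R1 -0.16  0.55 -0.16
R2 -0.17 -0.77 -0.15
```

Gating kept 94% of events; the CD38-high subclone carries 2.2-fold more
RelA after background correction (the generator's designed truth,
recovered by the pipeline), while cRel and RelB do not differ — and the
fingerprint shows the same picture in z-units: the subclones separate by
~1.3 pooled SDs on the RelA axis only.

The simulation side (`analysis/02_population_heterogeneity.py`, 25-cell
populations under a TME step) prints:

```
stimulated response (peak mean - basal mean), by population:
  nRelAp50 (baseline response 6.14, basal SD 0.92):
    RelA_x10   delta  51.39 <-- response amplified beyond baseline variability
    RelB_x10   delta   6.14
    baseline   delta   6.14
    cRel_x10   delta   0.08
```

— only increased RelA expression amplifies the nuclear RelA:p50 response
to TME activation beyond the population's inherent cell-to-cell
variability. `analysis/05_mutation_response.py` closes the loop: with
each virtual cell line's mutations included, every line but the
wild-type, low-RelA RIVA-like line loses its response:

```
lines responding beyond their basal cell-to-cell variability:
   RIVA (no mutations): fold 1.11, basal CV 0.07
```

## CLI

`nfkbfp synth|simulate|fingerprint|calibrate|recipe|validate` — thin
wrappers over the library; every command takes a seed and writes
delimited text. See `docs/methods.md` for the model, its assumptions,
parameter choices and known limitations.
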