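# Methods

This note documents the models and statistics implemented in `nfkbfp`, the
choices behind their parameters, and what the synthetic data used for
testing does and does not establish about real measurements.

## Reaction-network layer

Models are declarative tables (species, parameters, reactions) compiled to
a vectorised ODE right-hand side. Concentrations are nM, time is hours.
The rate-law dialect is deliberately closed:

| law | rate | use |
|---|---|---|
| `mass_action` | k · Π[reactant]^stoich | binding, conversion, degradation |
| `constant_source` | k | protein synthesis |
| `activation` | k · Π[reactant] · Π[modifier] | enzyme/input-driven steps |
| `hill_activation` | k · M^n / (K^n + M^n), M = Σ modifiers | induced synthesis, carrier-limited transport |

`hill_activation` is a Vmax-style law: reactants set stoichiometry only.
Modifiers may be species or *inputs* — parameters of class `input` whose
table value is the basal level and which a time-varying stimulus can
override. Integration uses LSODA (the IKK–IkB reactions are much faster
than synthesis/degradation, so a stiffness-switching method is required);
trajectories are clipped at zero and any excursion beyond ~100·atol
raises. Steady states are found by chunked integration until the relative
derivative norm max|dx/dt|/(|x|+1e-9) falls below 1e-6 /h, with an optional
Newton polish that is accepted only if it stays non-negative and close to
the integrated state; a 500 h horizon is the cut-off, and hitting it flags
(never silently accepts) the result.

## Core NF-kB model

22 species, 71 reactions, 51 constants + 2 inputs. The default dimer set
is RelA:p50, cRel:p50, RelB:p52 and p50:p50 (the p50 homodimer couples the
RelA and cRel branches through a shared p50 pool); any of the 15 subunit
pairs can be enabled in the build configuration, with generic weak
kinetics. Structure:

* constant-source synthesis per subunit (the expression-class parameters
  that population sampling, 10-fold experiments and 10^z cell-line scaling
  act on); p50 and p52 arise only by processing of p105 and (NIK-dependent)
  p100; p100 also sequesters RelB, and NIK releases it (the IkBd role).
* IkBa and IkBe bind the canonical dimers in both compartments; nuclear
  capture exports the dimer as a cytoplasmic complex. NEMO-IKK input
  degrades complexed (and free) IkB, releasing the dimer — the canonical
  activation route.
* free dimers enter the nucleus through carrier-limited (Michaelis)
  import with per-dimer capacities; export is slow and first order.

Because the published parameter tables of the models this network distils
are not reproduced here, all rate constants are authored values chosen so
that a documented set of qualitative behaviours holds simultaneously; the
tests assert exactly those behaviours rather than any numeric curve:

* a NEMO-IKK step releases a large RelA:p50 pulse (peak ≈ 1.6× basal at
  the default operating point, peaking ≈ 2 h after stimulus onset);
* 10× RelA expression amplifies the absolute stimulated response ≈ 8-fold
  while 10× cRel or RelB leave it unchanged or lower it (p50 competition);
* nuclear cRel:p50 is essentially stimulus-blind and its response is
  unchanged by 10× cRel or RelB;
* basal (steady-state) nuclear RelA:p50 is only weakly sensitive to the
  basal NEMO-IKK level (≈ +30% over a 20-fold input range), which is what
  lets chronically signalling mutants keep a near-normal resting state.

Three asymmetries carry these behaviours: IkBa synthesis is induced by
nuclear RelA:p50 with a steep Hill term (n = 4, K = 12 nM) and is strongly
IKK-degradable — it collapses during a stimulus and clamps the steady
state; IkBe is cRel:p50-specific, small, and nearly IKK-insensitive — it
holds cRel:p50 out of the stimulus path; and cRel:p50 binds p50 ~100×
tighter than RelA:p50, so its dimer pool is saturated in p50 and ignores
the free-p50 surge that follows IkB degradation.

Known limitation: a 10× RelA increase still perturbs the nuclear cRel:p50
response (mass-action coupling through liberated p50 and
monomer-vs-complex turnover differences). The invariants asserted for the
cRel axis therefore cover the baseline, 10×-cRel and 10×-RelB conditions.

Reporters: `nuclear_dimer_series` (free nuclear dimer) and
`total_subunit_abundance` — the stoichiometry-weighted sum over every
species containing a subunit, both compartments, with precursors counted
into their product pools (p105→p50, p100→p52) so totals are conserved
under processing. Totals are what a fixed/permeabilised total-protein
stain measures, and they are the simulated fingerprint's marker values.

## Receptor modules and mutations

TLR9 and BCR branches are separate small networks whose *active IKK*
outputs are summed (after simulating each branch) and fed to the core as
its NEMO-IKK input through a fixed scale (32 nM active IKK ≡ 1.0 input
unit, placing the resting combined output at the core's basal 0.05).

Both branches end in a three-state IKK cycle: inactive → active (driven by
TAK1) → refractory → inactive, with slow recovery (0.04 /h). A transient
stimulus converts the inactive reserve into a large active-IKK spike; a
*chronic* drive instead parks the pool in the refractory state, capping
basal active IKK at a low ceiling while emptying the recruitable reserve.
This single motif yields the mutation phenotypes:

| lesion | encoding | default magnitude |
|---|---|---|
| MYD88 L265P | MyD88 self-activation rate | ×25 (self-sustaining) |
| CD79B | basal BCR engagement set-point | set to 20 nM/h |
| TAK1 | TAK1 activation rate (both branches) | ×12 |

Magnitudes are authored: large enough to saturate their cascade (fold
change collapses toward 1), small enough that basal nuclear RelA:p50 stays
within one population SD of the unmutated line. CD79B alone acts only
through the modest basal-input elevation (its branch has no CpG response
to lose), so it reduces the stimulated fold change the least of the three;
the MYD88+CD79B combination abolishes the response.

The TLR branch additionally adapts at the receptor level (engaged TLR9 is
internalised faster than it is resynthesised), so even the wild-type CpG
response is a peak-and-decline, not a plateau.

## Populations and the two-phase protocol

Cell-to-cell variability is extrinsic only: each cell draws every
expression- and degradation-class parameter from Normal(μ, 0.11·μ)
truncated at zero *by resampling* (at 11% CV the sub-zero mass is ~10⁻²³,
so the truncation bias is nil and the distribution stays clean). Per-cell
streams come from `SeedSequence(seed, spawn_key=(cell,))`, so populations
are deterministic, order-independent, and extensible without resampling
earlier cells. Expression scalings (10-fold or 10^z) multiply the *base*
value before sampling and therefore persist through both phases.

Each cell runs a steady-state phase at constant basal input whose terminal
state seeds the stimulated time-course phase exactly. The base-parameter
steady state warm-starts every cell (sampled cells sit within ±11% of it),
which cuts the relaxation cost several-fold. Default sizes follow the
study design this reproduces: 25 cells for time courses, 1,000 for basal
fingerprints. Readout grids always contain the experimental anchors
(45 min, 2 h).

## Virtual cell lines

Expression z-scores map to parameter factors as 10^z (z = 0 → ×1,
z = 1 → ×10), computed per gene across a standardised cell-line library
(population-SD convention; the n vs n−1 difference is immaterial at the
library sizes used). Calibration to a measured fingerprint adjusts RelA
and RelB only: the candidate population is pooled with an unscaled
baseline population, fingerprinted, and the candidate's per-marker median
z is driven to the target by deterministic 1-D bisection on log10-scaling
(the map is monotone); default tolerance ±0.15 z-units. Targets outside
the achievable median-z range (bounded near ±1 for a two-population pool)
raise with the achievable range in the message.

The six shipped population presets (RIVA, U2932 R1, U2932 R2, HBL1,
patient-like, healthy-like) encode the qualitative fingerprint layout of
the measured populations — RelA rising RIVA < U2932 R2 < HBL1 < U2932 R1,
primary cells low in RelB — together with each line's known lesions
(HBL1: MYD88 L265P + CD79B; U2932: TAK1; RIVA: wild type). The patient
preset is unimodal (the measured sample's RelA bimodality is a flow-preset
feature, not simulated). Per-line basal NEMO-IKK levels are derived from
the line's mutated receptor modules rather than fixed by hand.

## Fingerprints

The fingerprint statistic: per-event isotype-MFI subtraction (negative
values preserved — clipping would bias low expressors), pooling of all
populations to be compared, then one z-standardisation per marker over the
pooled cells (population SD). Pooling strictly precedes standardisation,
so between-population differences survive as shifted label-conditional
distributions. Two isotype procedures coexist deliberately: the per-event
subtraction above (fingerprints) and the sample-level MFI ratio
(reporting); they are distinct functions. Simulated fingerprints use
per-cell total subunit abundances and skip the isotype step (simulation
has no staining background).

Gating: FSC-A/SSC-A quantile band (1%–99.5%) for lymphocytes,
FSC-H/FSC-A ratio band (0.85–1.15) for singlets, and an optional CD20-high
gate whose default threshold is the midpoint of a deterministic 1-D
2-means split of log-CD20 (robust to the B-cell fraction, unlike a fixed
quantile); absolute cuts are available in the configuration. Subclone
comparison reports the corrected-MFI ratio (CD38-high over CD38-low)
together with a two-sided event-level Mann-Whitney U — the effect size is
never reported without the test, and the test never without the effect
size, since at flow-scale event counts minuscule shifts are "significant".

## Synthetic data

Flow samples are per-subpopulation log-normal channel draws plus an
additive log-normal staining background; the paired isotype table re-draws
the marker channels from the background alone. Truth labels (subpopulation,
B-cell, doublet) ride in a sidecar so gate sensitivity and fold-change
recovery are exactly computable. The default two-subclone preset places
its R1 RelA median at 2316.9 (R2 at 1050, background median 50) — the R1
value is calibrated against the additive-background model so that the full
gating + isotype-correction + MFI pipeline recovers a corrected-MFI fold
of 2.2, the measured subclone difference this preset emulates. The
expression-library generator draws genes independently log-normal
(n = 21 lines by default), emulating heterogeneous, uncorrelated subunit
expression.

What the synthetic data does *not* emulate: spectral spillover and
compensation, autofluorescence structure, instrument drift, doublet
morphology beyond the FSC-H ratio, or any correlation between surface
markers and NF-kB content other than the designed subclone differences.
Passing the recovery tests shows the pipeline's statistics are correct on
data of known structure, not that gating thresholds are optimal for any
particular instrument.

## Numerical and reproducibility choices

Solver tolerances default to rtol 1e-6 / atol 1e-8 (1e-9/1e-12 in
closed-form tests). Every stochastic step is a pure function of an integer
seed; experiment recipes hash their configuration into a provenance
manifest (config hash, seed, package version, per-stage cell counts) that
suffices to re-run bit-identically. Problem sizes in the shipped
experiment recipes are the study-design sizes (25-cell time courses;
6 × 1,000-cell fingerprint simulations, about two minutes on one core);
tests that only need a direction or an invariant use smaller populations
(12–60 cells), chosen so sampling error is far below the asserted margins.
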