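# Methods

## The labeling model

The simulator tracks, for every metabolite pool, a probability
distribution over *positional* ¹³C labeling states — bitmasks over the
molecule's carbons — rather than mass-only M+X states.  Positional states
are necessary for correctness at two places: decarboxylation steps remove
one *specific* carbon (so the mass lost depends on where the label sits),
and succinate/fumarate are symmetric molecules whose orientation is
randomized by the enzymes acting on them.  Both effects change the MID in
ways a mass-only convolution cannot represent.  The reported object is
nevertheless always the MID (the popcount marginal); no positional readout
is claimed beyond it.

Atom maps are fixed: glucose cleaves into two pyruvates (C1–C3 reversed,
C4–C6 in order); pyruvate dehydrogenase releases C1 and passes C2,C3 to
acetyl-CoA; citrate synthase concatenates oxaloacetate (o1..o4) with the
acetyl carbons (a1,a2); the citrate → α-ketoglutarate step releases the
OAA-derived o4 (α-KG = o1,o2,o3,a1,a2) and the α-KG → succinate step
releases k1 = o1.  Taking the two CO2 from opposite ends of the OAA moiety
is what reproduces both canonical observations simultaneously: first-turn
[4,5-¹³C]α-KG / M+2 succinate from [1,2-¹³C]acetyl-CoA, and second-turn
M+3 succinate/fumarate/malate/aspartate from either orientation of a
scrambled M+2 oxaloacetate (alongside M+3/M+4 α-KG).  Succinate→fumarate
and fumarate→malate average the state with its carbon reversal (50/50
orientation scrambling), which is equivalent at the MID level to the
molecular symmetry.

### Time as turns

The wet experiment is a 90-minute non-steady-state incubation.  Rather
than fitting rate equations (no kinetic constants are available), time is
discretized into TCA "turns": each turn replaces every pool by a convex
mixture of its retained distribution (fraction ρ per pool) and its inflow
distributions.  Within a turn, pools update sequentially in pathway order,
and the citrate-synthase condensation deliberately uses the oxaloacetate
distribution from *before* the turn — this makes one turn carry acetyl
label exactly one span around the cycle and yields the M+2 → M+3/M+4
hierarchy of successive turns.  The default is 4 turns with partial
retention, which leaves all pools visibly short of isotopic steady state,
emulating dynamic labeling.  Turn counts and ρ are configurable; nothing
in the analysis chain depends on this choice.

### Mixing parameters

All routing is expressed as per-turn convex mixture fractions
(dimensionless, in [0,1]), not fluxes:

| parameter | meaning | control | disease-like |
|---|---|---|---|
| `f_glycolysis` | pyruvate inflow from medium glucose | 0.50 | 0.40 |
| `f_accoa_dilution` | unlabeled acetyl-CoA inflow | 0.10 | 0.10 |
| `w_cit`, `w_glu_in`, `w_dil` | α-KG sources: citrate / glutamate (GDH/AAT) / dilution | 0.50/0.30/0.20 | 0.62/0.15/0.23 |
| `f_pag` | glutamate from glutamine (glutaminase) | 0.20 | 0.40 |
| `f_glu_from_akg` | glutamate back from α-KG (GDH/AAT) | 0.35 | 0.50 |
| `f_uptake_glu` | glutamate from medium | 0.10 | 0.10 |
| `f_uptake_gln` | glutamine from medium | 0.40 | 0.40 |
| `f_got` | OAA↔aspartate exchange | 0.50 | 0.50 |
| `f_gs` | glutamine from glutamate (astrocytes only) | 0 (0.25) | 0 (0.35) |
| ρ (cycle pools) | retention per turn | 0.30 | 0.15 |
| pool sizes | nmol/mg protein (glutamate 61, glutamine 12 control / 6 disease, …) | | |

Neurons express no pyruvate carboxylase, so there is no pyruvate → OAA
route; anaplerosis enters only through the glutamine/glutamate axis.
Astrocyte mode enables glutamine synthesis (`f_gs`) and raises glutamate
uptake; pyruvate carboxylase itself is still not modeled, since the
glucose tracer is not simulated in astrocytes.

The disease preset encodes *directions*, not fitted values — the source
observations are directional (reduced glycolytic labeling, increased
cycling, glutaminase up, GDH down, glutamine pool halved) and publish no
flux magnitudes to fit.  Magnitudes were chosen once so that every
direction holds in the noiseless truth and remains detectable at the
simulated noise level; some effects (notably the cycling-ratio increase,
roughly 2–4× here versus ~25% in the motivating data) are therefore larger
than their real-world counterparts.  Two constraints shaped the preset
rather than any single observation: the product `w_glu_in ×
f_glu_from_akg` is held nearly equal across groups, which pins glutamate
M+5 under the glutamate tracer (the "transport intact" observation) while
still letting both factors move in their documented directions; and the
increased `f_glu_from_akg` is attributed to AAT-mediated exchange, which
the motivating proteomics found increased even as GDH fell.

### Tracer configurations

2.5 mM [U-¹³C]glucose; 0.5 mM [U-¹³C]glutamine + 2.5 mM unlabeled glucose;
0.25 mM [U-¹³C]glutamate + 2.5 mM unlabeled glucose.  Tracer purity
(default 0.99) is all-or-nothing per molecule; per-position impurity is
not modeled.  Concentrations are recorded metadata — labeling is routed by
the mixture fractions, not by kinetics (a deliberate non-goal).

## Oracles

Two independent implementations check the engine: an exhaustive
enumeration over source-combination paths (tuple masks and dictionary
arithmetic, guarded to ≤ 4 turns) and a molecule-level Monte Carlo sampler
(≥ 10⁵ molecules, binomial standard errors, seeded).  The enumeration must
agree to 1e-9 across a parameter grid and all three tracers; the sampler
to 3 SE.  Label is balanced every turn: ¹³C drawn from sources equals the
pool-weighted ¹³C change plus displaced ¹³C plus ¹³C released as CO2, to
1e-9 in pool-size-weighted carbon units.

## Measurement model

Observed abundance vector = (C · MID) × pool size × lognormal(cv) + an
optional zero-mean additive floor, truncated at 0, where C is the
natural-abundance matrix.  The default cv is 5%, per channel and
independent across channels and replicates — a simplification: real GC-MS
channel noise is correlated within a scan and has ion-count statistics at
low intensity, so passing tests here bound only multiplicative-noise
behavior.  Unlabeled-standard tables are generated through the same
forward model from a pure M+0 truth.  All stochastic paths require seeds;
identical seeds give byte-identical datasets.

The cohort layout mirrors the motivating study: 3 patient-derived lines vs
3 isogenic control lines, 6 replicate cultures per line and condition
(pooled n = 18 per group), lines within a group sharing a parameter set —
so the synthetic data contain no line-level biological variance; between-
line variance in real data would widen every test.

## Natural-abundance correction

Column j of a correction matrix is the predicted observed distribution of
a pure M+j species.  Empirical mode builds every column by shifting the
normalized envelope of a measured unlabeled standard — a *shift-invariance
assumption* whose error in column j is O(j · p13) per entry, because the j
labeled carbons can no longer contribute natural-abundance mass (the
matrix-level disagreement with the binomial construction reaches ≈ n·p13
in the last column; at these envelope widths the practical effect on
corrected MIDs is below measurement noise).  Theoretical carbon mode uses
the binomial envelope of the n−j unlabeled backbone carbons at
p13 = 0.0107; formula mode additionally convolves fixed isotope patterns
of H, N, O, S, Si and any derivatization carbons, and is off by default
because the empirical route is the method of record.  Mass channels beyond
M+n are truncated and columns are *not* renormalized, losing < 0.1% of a
column's mass.  Inversion is non-negative least squares by default
(`solve_clip` — plain solve with clipping — is retained for comparability
with legacy spreadsheet corrections); the corrected vector's sum is
returned as total abundance for pool arithmetic.

## Statistics

Pooled-variance unpaired t tests per stratum with Bonferroni–Dunn
correction (raw p × family size, capped at 1); the family is the set of
strata actually tested, and is defined per tracer condition in the
signature report.  Welch's test is available behind `equal_var=False`.
Two-way ANOVA uses Type II sums of squares (robust default for unbalanced
layouts) from an OLS fit with interaction; pairwise group contrasts within
each second-factor level use the model residual mean square with Šidák
adjustment, and zero-residual-variance inputs are flagged degenerate
rather than producing 0/0 F statistics.  Cycling ratios are computed per
replicate and then summarized (never on pooled means); the M+1 term stays
in the numerator because the defining formula lists it, even though a
uniformly labeled glucose tracer cannot produce first-turn M+1; M+0 is
excluded.  Contrasts pool replicates across the lines of a group; per-line
contrasts are available through the same `multiple_t_tests` interface by
stratifying on `line`.

The signature report evaluates eight flags, each backed by its comparison
rows: difference flags need adjusted p < α *and* the documented direction
(multi-stratum flags need every member to agree); the "glutamate M+5
unchanged" flag needs adjusted p ≥ α.  Missing assays yield
"not evaluable" rather than false.

## Bioenergetics

The generated schedule is the glycolysis-assay layout: measurement cycles
of 3 min mix + 3 min measure, three basal cycles, oligomycin, exactly one
measurement, rotenone/antimycin, two final cycles.  Segmentation takes
basal = last pre-oligomycin point, post-oligomycin = the single following
point, non-mitochondrial/non-glycolytic = minimum after the second
injection.  The final post-rotenone/antimycin ECAR point of *each well*
(not a group mean) is that well's 100% reference.  Coupling efficiency is
computed per well and then averaged.  Maximal respiration / spare capacity
(FCCP) metrics are out of scope — the schedule has no uncoupler injection.

## Numerical choices and degenerate inputs

Distributions are validated to sum to 1 within 1e-9 after every turn.
Correction requires a strictly positive observation vector and a
non-singular matrix (`solve_clip`); nnls output is renormalized.
Calibration requires ≥ 3 standard levels and a positive slope; areas below
the calibrated range are flagged, not rejected.  `cycling_ratio` returns a
flagged NaN when M+2 is zero.  Seeds are mandatory for every stochastic
generator; the pipeline derives all of its randomness from one seed.

## Known limitations

- Single compartment per cell type: no astrocyte–neuron shuttling, and one
  glutamate pool even though exogenous and glutamine-derived glutamate are
  discussed as partially separate pools in the field; separate inflow
  weights stand in for compartmentation.
- Turn discretization is not kinetics: absolute labeling magnitudes track
  the mixture fractions, not enzyme rates, so only directions and ratios
  are meaningful points of comparison with real data.
- Measurement noise is independent lognormal; no isobaric interference,
  retention-time drift, or detector saturation is simulated, and raw
  chromatograms are out of scope (input begins at integrated isotopologue
  abundances).
- The disease preset's effect sizes are deliberately detection-friendly;
  passing the signature recovery says the *pipeline* recovers directions
  at the simulated noise, not that real effect sizes are this large.
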