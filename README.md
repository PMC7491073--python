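# tracemet

¹³C metabolic mapping for cultured neural cells: simulation and analysis of
stable-isotope tracing experiments through glycolysis, the TCA cycle and
the glutamate–glutamine axis, in the style used to characterize energy
metabolism in patient-derived neurons (e.g. CHMP2B-mutant frontotemporal
dementia lines versus CRISPR-corrected isogenic controls).

## What it does

A short (90-minute-scale, non-steady-state) incubation with 2.5 mM
[U-¹³C]glucose, 0.5 mM [U-¹³C]glutamine or 0.25 mM [U-¹³C]glutamate labels
intracellular metabolites in characteristic patterns: glucose-derived
[1,2-¹³C]acetyl-CoA condensing with unlabeled oxaloacetate makes M+2 cycle
intermediates on the first TCA turn, M+3/M+4 species on later turns, while
glutamine enters as glutamate M+5 via glutaminase.  The package covers the
complete computational chain of such an experiment:

- **`tracemet.network` / `tracemet.propagate`** — a positional-isotopomer
  simulator: each pool is a distribution over carbon bitmasks, propagated
  turn by turn through explicit atom maps (decarboxylations lose a specific
  carbon; succinate and fumarate undergo 50/50 orientation scrambling).
  Mass-only propagation is provably wrong for these steps, which is why the
  simulator is positional even though only mass-isotopologue distributions
  (MIDs) are reported.
- **`tracemet.oracle`** — independent re-computations of the same MIDs by
  exhaustive path enumeration and by seeded molecule-level Monte Carlo.
- **`tracemet.measure` / `tracemet.instruments`** — forward measurement
  models: natural-abundance convolution, pool-size scaling, lognormal
  noise; extracellular-flux (ECAR/OCR) traces with an
  oligomycin → rotenone/antimycin injection schedule; HPLC-style
  amino-acid peak areas with calibration-standard series.
- **`tracemet.correction`** — natural-abundance correction by non-negative
  least squares against empirical (unlabeled-standard) or theoretical
  (binomial / elemental-formula) correction matrices.
- **`tracemet.enrichment`** — labeling (%) per isotopologue, absolute
  isotopologue amounts, amino-acid quantification, and the TCA **cycling
  ratio** ([M+1] + [M+3] + … + [M+n]) / [M+2]: second-and-later-turn
  labeling relative to first-turn labeling, a proxy for cycle turnover.
- **`tracemet.bioenergetics`** — trace segmentation and the respiration
  decomposition: ATP-linked = basal − post-oligomycin, mitochondrial
  basal = basal − non-mitochondrial, **coupling efficiency** =
  100 × ATP-linked / mitochondrial basal; ECAR normalized per well to its
  final non-glycolytic value.
- **`tracemet.stats` / `tracemet.pipeline`** — pooled-variance t-test
  families with Bonferroni–Dunn correction, two-way ANOVA (Type II) with
  Šidák-adjusted pairwise contrasts, mean ± SEM summaries, and a
  machine-readable **signature report** of the disease phenotype
  (glycolysis ↓, TCA cycling ↑, glutamine route ↑, glutamate oxidation ↓,
  glutamine pool ↓, coupling efficiency ↓, ECAR ↓, glutamate transport
  unchanged).

No experimental data ships with the package; the simulator doubles as the
data source for testing every downstream stage.

## Worked example

```python
from tracemet.pipeline import run_pipeline

result = run_pipeline(seed=1)          # 3 disease + 3 control lines,
print(result.report.text())            # n=6 replicates, cv=5%, 3 tracers
```

```
Disease-signature report (alpha = 0.05)
--------------------------------------------
  lactate_m3_down                  YES
  cycling_ratios_up                YES
  glutamine_derived_enrichment_up  YES
  glutamate_m5_unchanged           YES
  glutamate_derived_m4_down        YES
  glutamine_pool_down              YES
  coupling_efficiency_down         YES
  ecar_down                        YES
  8/8 flags present
```

The backing comparisons are plain tidy tables.  For this seed the glucose
condition gives lactate M+3 labeling of 36.3 ± 0.4 % in the disease group
versus 45.9 ± 0.4 % in controls (adjusted p ≈ 1e-17, pooled across lines):
the simulated glucose hypometabolism.  Glutamate cycling ratios rise from
0.065 to 0.137; recovered coupling efficiencies are 71.3 ± 0.9 % versus
77.9 ± 0.6 %; quantified glutamine pools are 6.1 versus 11.9 nmol/mg
protein.  `run_pipeline(seed=1, null=True)` runs the same machinery on a
control-vs-control cohort and flags none of the difference findings.

The same chain is scriptable from a shell:

```sh
tracemet simulate --seed 1 --out-dir sim/
tracemet correct --samples sim/samples.csv --standards sim/standards.csv --out corrected.csv
tracemet enrich --corrected corrected.csv --out-dir enriched/
tracemet bioenergetics --traces sim/traces.csv --injections sim/injections.csv --out wells.csv
tracemet run-all --seed 1 --out-dir results/
```

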