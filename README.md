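# vulntrend

Analysis pipeline for studying **selective motor-neuron vulnerability** in
spinal muscular atrophy (SMA). Motor-neuron pools innervating different
muscles degenerate at very different rates in SMA — e.g. the pool supplying
the extensor digitorum longus (EDL) is disease-resistant, the gastrocnemius
(GS) pool intermediate, and the tibialis anterior (TA) pool highly
vulnerable. `vulntrend` implements the computational side of a workflow
that asks *why*: which transcripts track vulnerability across ordered
pools, which pathways they enrich, and whether the downstream bioenergetic
and neuromuscular phenotypes follow.

The package is aimed at wet-lab groups producing this kind of data
(microarray/RNA profiles of labelled motor-neuron pools, Seahorse plate
runs, qPCR plates, blot densitometry, axon/endplate scoring sheets) who
want a scripted, testable replacement for spreadsheet analysis.

## What it computes

**Vulnerability trending filter** (`vulntrend.trending`). For a log2
expression matrix over three ordered groups (resistant → intermediate →
vulnerable), a transcript is called by two cut-offs:

1. a two-sided Welch t-test between the extreme groups at raw *p* < α
   (default 0.05), with log2 fold-change `mean_res − mean_vul`;
2. a monotone-trend requirement: the intermediate-group mean must lie
   strictly between the extremes, in the direction of the fold-change.

Transcripts passing both are *protective* (higher in the resistant pool) or
*harmful* (higher in the vulnerable pool); BH q-values are reported
alongside but do not gate calls.

**Over-representation analysis** (`vulntrend.enrichment`). Hypergeometric
upper-tail test of a call set against GMT gene-set collections:
*p* = P(X ≥ k) with universe N (the measured transcripts), set size K, hits
n, overlap k; Benjamini–Hochberg FDR across sets.

**Mito stress-test parameters** (`vulntrend.flux`). From per-well OCR
traces through basal → oligomycin → FCCP → antimycin/rotenone phases, with
B6 the 6th basal cycle, Omin the lowest oligomycin cycle, Fmax the highest
FCCP cycle and AAlast the final antimycin/rotenone cycle:

    basal = B6 − AAlast        atp_linked  = B6 − Omin
    proton_leak = Omin − AAlast maximal    = Fmax − AAlast
    spare = Fmax − B6

Wells with negative ATP-linked respiration are excluded from group
summaries (and only those); groups are compared by Welch t-tests.

**ΔΔCt and densitometry** (`vulntrend.quant`). Standard 2^−ΔΔCt relative
quantification against a reference gene (β-actin in the emulated study)
with the control-condition mean ΔCt as baseline, and loading-control
ratio normalization for western-blot band intensities.

**Phenotype scoring** (`vulntrend.phenotype`). Per-embryo motor-axon
classes (normal / branched / severe, 12 axons per embryo) and per-muscle
endplate occupancy (fully / partially / vacant, ≥80 endplates per muscle),
converted to per-unit percentages and compared by Welch t-tests, plus a
dose–response monotonicity summary.

**Synthetic data** (`vulntrend.synthetic`). Seeded generators for every
stage — planted trending transcripts on a null background, OCR traces with
known respiration components, Ct tables implying chosen fold-changes,
multinomial axon counts — so the whole pipeline runs and is tested without
any external download. At zero noise each generator's planted truth is
recovered exactly.

## Worked example

```python
from vulntrend.synthetic import TrendingSimSpec, simulate_expression
from vulntrend.trending import run_trending

spec = TrendingSimSpec(n_transcripts=1000, n_per_group=3,
                       n_planted_protective=50, n_planted_harmful=50,
                       effect_log2fc=2.0, noise_sd=0.25, seed=1)
study, truth = simulate_expression(spec)
result = run_trending(study, alpha=0.05)
print(result.summary())
```

prints

```
{'alpha': 0.05, 'n_transcripts': 1000, 'n_significant': 132,
 'n_protective': 63, 'n_harmful': 59}
```

132 of 1000 transcripts pass the extreme-group test at p < 0.05; the trend
cut-off prunes these to 63 protective and 59 harmful calls. All 100 planted
transcripts are recovered (the extra calls are the expected false positives
at raw p < 0.05 — compare `result.table["q_value"]`). The same run is
available from the shell:

```sh
vulntrend trend --matrix study_matrix.tsv --samples study_samples.csv \
                --config study_groups.yaml --alpha 0.05 --out out/
```

A two-group respirometry comparison at the study's plate size
(14 wells/group, noise sd 2 pmol O2/min):

```python
from vulntrend.synthetic import FluxSimSpec, simulate_flux
from vulntrend.flux import FluxPlate, derive_plate, compare_groups

ctrl  = simulate_flux(FluxSimSpec(group="control", seed=1))
morph = simulate_flux(FluxSimSpec(true_basal=60.0, true_atp_linked=40.0,
                                  true_maximal=100.0, group="morphant",
                                  seed=2))
params = derive_plate(FluxPlate.concat([ctrl, morph]))
print(compare_groups(params, "basal"))
```

reports control 100.29 ± 0.45 vs morphant 60.54 ± 0.56 pmol O2/min
(n = 14 each, Welch p ≈ 1.4e-27): the planted 40% reduction in basal
respiration is recovered with well-calibrated uncertainty.

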