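# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions and known limitations.

## Trending analysis

**Model.** Three motor-neuron pools ordered by disease vulnerability
(resistant, intermediate, vulnerable), each with ≥2 replicate profiles of
log2 expression. Per transcript, two cut-offs:

1. *Significance*: two-sided t-test between the two extreme groups on the
   log2 values, called at raw p < α. The default statistic is Welch
   (unequal variances); a pooled-variance Student option exists
   (`test="student"`) because vendor array-analysis suites differ and the
   exact statistic behind historical gene lists is rarely recoverable.
   With 3 replicates per group neither variant has much power below ~1.5
   log2 units of effect; the filter is intentionally a screen, not a
   calibrated discovery procedure.
2. *Trend*: the intermediate mean must lie **strictly** between the extreme
   means, on the side implied by the sign of the fold-change. "Between" is
   ordinal, not a numeric-midpoint window: requiring proximity to the exact
   midpoint would make calls depend on an arbitrary bandwidth. An optional
   `gap` parameter (default 0) tightens the rule to demand a margin. Exact
   ties fail — equality is not a trend, and under any continuous noise
   model ties have probability zero, so the choice only matters for
   degenerate (e.g. integer-quantized) input.

Multiple testing: calls are gated on raw p as is conventional for this kind
of screen; BH q-values are computed over all transcripts and reported so a
user can apply an FDR cut downstream. α is accepted in [0, 1): α = 0 is a
valid degenerate screen that calls nothing.

Degenerate data: a transcript constant in both extreme groups gets p = 1
when the means are equal and p = 0 when they differ (a deterministic
difference); this keeps the zero-noise limit of the generator exactly
recoverable.

Type-I behaviour: under a global null the *call* rate is well below α,
because a significant extreme-group difference must additionally draw the
independent intermediate mean into the matching open interval (empirically
≈ α/2 at these sample sizes). The acceptance suite checks the rate stays
≤ α; it does not try to make the two filters jointly calibrated.

## Over-representation analysis

One-sided hypergeometric upper tail, P(X ≥ k) = `hypergeom.sf(k−1, N, K, n)`.
The universe defaults to the transcripts present in the loaded matrix —
the population actually eligible to be called — not the union of the GMT
collection; this is configurable. Gene identifiers match by exact string
(optional upper-casing); no ortholog or probe mapping is attempted. Sets
are restricted to the universe first, then filtered to sizes in
[min_set_size, max_set_size] (defaults 3 and 2000) to avoid degenerate and
uninformative tests. FDR across the retained sets is Benjamini–Hochberg.

A caution recorded here because a test documents it: the BH step-up map is
**not idempotent**. For p = (0.25, 1) the adjusted vector is (0.5, 1), and
re-adjusting that vector yields (1, 1); R's `p.adjust(..., "BH")` behaves
identically. q-values are therefore an end product, never to be fed back
through the adjustment.

## Respiration parameters

The derivation uses single designated cycles — the 6th basal measurement
(1-based acquisition order), the minimum of the oligomycin phase, the
maximum of the FCCP phase, the last antimycin/rotenone measurement — and
the five subtractions listed in the README. Two identities follow
algebraically and are enforced as tests to machine precision:
`basal = atp_linked + proton_leak` and `spare = maximal − basal`.

*Exclusion.* Only a negative ATP-linked value excludes a well (a well whose
oligomycin floor exceeds its 6th basal reading is physiologically
uninterpretable); negative proton leak or spare capacity is retained with a
warning, since those can arise from ordinary noise around small true
values. Exclusion is monotone in the oligomycin level: raising oligomycin
readings can only move wells from retained to excluded.

*Strict vs lenient basal.* Strict mode (default) requires ≥6 basal cycles.
Runs acquired with shorter basal windows can opt into `lenient_basal`,
which substitutes the last available basal cycle and logs the fallback.

*Known limitation — extreme-statistic bias.* Because Omin and Fmax are the
min/max of (by default) 3 noisy cycles, they are biased low/high by
σ·E[max of 3 standard normals] ≈ 0.846 σ under i.i.d. Gaussian measurement
noise of sd σ. At the default σ = 2 pmol O2/min this shifts ATP-linked and
maximal respiration up, and proton leak down, by ≈1.7 pmol O2/min — of the
same order as a 14-well group's standard error. Basal and spare-minus-bias
relations inherit accordingly; basal itself, built from single designated
cycles, is unbiased. This is a property of the published derivation rule,
not of its implementation; *between-group comparisons are unaffected* when
both groups share a schedule and noise level, because the bias cancels in
the difference. The test suite documents the bias by asserting a 3-SEM
recovery band that the biased parameters genuinely fail.

No per-well normalization (protein, cell count) is applied: the emulated
design holds biological material per well constant, so OCR units are
carried through as pmol O2/min.

## ΔΔCt and densitometry

ΔCt_s = Ct(target, s) − Ct(reference, s); the ΔΔCt baseline is the
arithmetic mean ΔCt over control samples (the standard pooled-baseline
convention; a per-sample baseline is not defined without paired designs).
RQ = E^−ΔΔCt with amplification efficiency E fixed at 2 by default — most
validated primer sets sit close enough to 100% that the plain ΔΔCt form is
the norm — with an efficiency-corrected option for primers that do not.
By construction the control group's *geometric* mean RQ is exactly 1.
Invariances that hold exactly and are property-tested: adding a constant
to every Ct of one sample cancels through the reference gene; adding one
cycle to every target Ct halves every RQ.

Densitometry: per-lane ratio target/loading (loading intensity must be
positive), group means ± SEM, Welch t-test, and the relative change of the
second group versus the first.

## Phenotype scoring

The unit of analysis is the embryo (axon scheme, 12 axons each) or the
muscle (endplate scheme, ≥80 endplates expected; fewer triggers a warning,
zero is an error) — never the individual axon/endplate, which would
pseudo-replicate. Percentages per unit sum to 100 by construction.
Comparisons are unpaired two-tailed Welch t-tests on per-unit percentages;
no arcsine or logit transform is applied, keeping the reported means
interpretable as percentages (at n = 20 units the t-test is robust to the
mild non-normality of multinomial proportions). Group labels are resolved
only at comparison time, so scoring can proceed on blinded/coded tables.

Endplate classification: vacant at exactly 0 coverage, partially occupied
below 50%, fully occupied at ≥50%. Published class definitions ("entirely"
vs "<50%") leave 50–99% coverage unassigned; the ≥50% rule is this
package's documented decision and the threshold is a parameter.

Dose–response: per-dose mean percentage of a category with a non-strict
monotonicity flag (ties count as monotone), requiring strictly increasing
dose values.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)`; identical
spec + seed is bitwise-reproducible.

* **Expression**: planted protective transcripts get means
  (baseline + effect, baseline + position·effect, baseline) across
  (resistant, intermediate, vulnerable); harmful transcripts mirror this;
  nulls share one mean. Noise is i.i.d. Gaussian on the log2 scale —
  the simplest model consistent with t-testing log2 values. Defaults:
  3 replicates/group, effect 2 log2 units, sd 0.25,
  intermediate position 0.5 ("midway" operationalized as the midpoint).
* **Flux**: phase plateaus assembled from true components
  (basal 100, ATP-linked 70, maximal 160, non-mitochondrial floor 20,
  all pmol O2/min) with the 6/3/3/10 cycle schedule, 14 wells/group,
  Gaussian noise sd 2 per measurement.
* **Ct tables**: target Ct lowered by log2(fold) per planted fold-change,
  constant reference gene, optional Gaussian Ct noise; 3 replicates per
  condition.
* **Phenotype counts**: one multinomial draw per embryo (12 axons,
  20 embryos/group by default).

`noise_sd = 0` is accepted everywhere as the degenerate noise-free limit;
negative noise is rejected.

What the generators do **not** emulate — and hence what green tests do not
establish about real data: probe-level effects and normalization artefacts
(inputs are assumed already summarized to log2 expression), correlated or
heteroscedastic noise, batch structure, injection-response kinetics within
an OCR phase (plateaus are flat), primer-efficiency variation, or
inter-animal overdispersion beyond multinomial sampling. Recovery rates
measured on synthetic data are best-case figures for data matching these
assumptions.

## Numerical conventions

* Zero-variance two-sample tests: equal means → t = 0, p = 1; unequal
  means → t = ±inf, p = 0.
* Enrichment tables sort by p ascending with set-id as the deterministic
  tie-break; ranked trending tables sort by |log2fc| descending with
  transcript-id tie-break (stable under input permutation).
* Min/max within an OCR phase need no index tie-breaking: only the value
  enters the subtractions.
* Matrix loads reject missing values by default; an explicit
  `missing="drop"` policy removes incomplete rows with a logged count.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at the emulated
study's own scale (1000-transcript screens over 50 simulated studies,
14-well plates over 200 seeds, 20-embryo groups over 200 seeds), which
keeps a full run in the seconds-to-a-minute range on one CPU while leaving
Monte-Carlo error well below the decision thresholds being checked.
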