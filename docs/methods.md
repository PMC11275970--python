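# Methods

## Measurement model and deconvolution

A bisulfite (BS) array channel reads the fraction of cytosines carrying
*either* 5mC or 5hmC; an oxidative-bisulfite (oxBS) channel reads 5mC
only. Treating the paired β values as binomial-type proportions with
effective weights n_BS, n_oxBS (read-equivalents; default 1, i.e. the
unweighted moment solution), the per-cell log-likelihood is

    L(m, h) = n_BS [β_BS log(m+h) + (1−β_BS) log(1−m−h)]
            + n_oxBS [β_oxBS log m + (1−β_oxBS) log(1−m)]

maximized over the simplex {m ≥ 0, h ≥ 0, m + h ≤ 1}, with the convention
0·log 0 = 0. Because L separates into a BS term in t = m + h and an oxBS
term in m with the constraint m ≤ t, the maximizer is closed-form:

* β_BS > β_oxBS (interior): m̂ = β_oxBS, ĥ = β_BS − β_oxBS;
* β_BS ≤ β_oxBS (boundary): ĥ = 0 and m̂ is the weight-pooled mean
  (n_BS β_BS + n_oxBS β_oxBS)/(n_BS + n_oxBS). Equality is flagged
  `boundary_h0` because ĥ = 0 there is a projection onto the edge.

Boundary cells are *estimated*, not discarded, so the downstream
"mean β_hmC" filter stays well defined; a `boundary_as_missing` switch
reproduces the stricter convention some pipelines use. Missing input in
either channel propagates to missing output. Feasibility is enforced to
1e-12; tests compare the closed form against an exhaustive 10⁻⁴-lattice
maximization (made exact at lattice resolution by a cumulative-max scan
over the separable terms).

## QC stages and thresholds

Applied in fixed order, each recomputed on the survivors of the previous
stage; every comparison is strict (>):

| stage | rule | default |
|---|---|---|
| failed samples | fraction of probes with detection p > 0.01 | > 0.10 |
| failed probes | fraction of samples with detection p > 0.01 | > 0.05 |
| masked probes | manifest `masked` flag (cross-reactive / SNP) | — |
| high-glial samples | estimated glial proportion | > 0.50 |
| low-level filter (post-MLE) | across-sample mean β_mC or β_hmC | < 0.01 removed |

Failure rules pool both channels' detection matrices (union of flags) by
default: a probe or sample unusable in either channel cannot enter the
paired deconvolution. Per-channel modes are available in `QCConfig`. The
low-level filter ignores missing entries in the mean and excludes probes
with no data at all; a mean of exactly the cutoff is kept (removal is
strict-<, so the equality case — measure zero in practice — is resolved in
favor of keeping). The filter yields three probe sets (β_mC, β_hmC,
common); the interaction model runs on the common set, where both marks
are analyzable.

## Interaction model

Per probe, one mC row (modtype 0) and one hmC row (modtype 1) per sample
with both values present; samples missing either mark are dropped so the
pairing is preserved, and probes with fewer than 3 complete pairs per
group are skipped. Values are clamped into [ε, 1−ε]. The model is a
beta-family mixed regression with a logit mean link, constant precision φ,
and a sample-level normal random intercept, fit by maximizing the
Gauss–Hermite-marginalized likelihood (20 nodes) with L-BFGS-B on
(b0..b5, log φ, log σ_u), analytic gradients, and moment-based starts from
an OLS fit on logits. Glial proportion and PMI are centered and scaled by
default (this rescales b4/b5 only; the interaction test is unaffected).
Constant covariates are dropped with a warning.

### Why cluster-robust inference

The deconvolution makes the two outcomes of a sample share the oxBS
measurement with opposite signs (β_m = β_oxBS, β_h = β_BS − β_oxBS), so
their errors are *negatively* correlated within a sample whenever
measurement noise dominates biological sample-to-sample variation. A
nonnegative-variance random intercept can only model positive sharing:
σ_u collapses to its bound, the likelihood treats the pair as independent,
and the observed-information Wald SE for the interaction underestimates
the variance of the paired contrast — in simulation the nominal 5% test
rejected ~25% of true nulls. The default therefore pairs the ML point
estimates with a cluster-robust (sandwich) variance, samples as clusters,
a G/(G−1) small-sample factor, and a t(G−1) reference — the standard
finite-sample treatment for cluster-robust Wald tests. This combination is
calibrated in simulation (type-I ≈ 0.04–0.05 at nominal 0.05) and remains
valid when within-pair correlation is positive, as expected on real data
with biological variability. The observed-information SE with a normal
reference is retained as `se_method: observed`.

Parameters sitting on an active bound (typically log σ_u) are excluded
from the curvature and variance computations; if the Hessian is still
singular the variance-component directions are dropped before inversion.
Non-converged probes carry no p-value and are excluded from the
Benjamini–Hochberg family (undefined p-values cannot enter the step-up);
BH is computed over converged probes and reported in input order. The
p-value histogram diagnostic labels the converged p's `uniform-ish`,
`anti-conservative` (first-bin excess, one-sided binomial test at 0.01),
or `conservative` (last-bin excess); on a mixed cohort the expected shape
is anti-conservative — uniform with an excess of small p-values.

### Numerical choices

* Clamp ε = 10⁻³ (configurable in (0, 0.01)). Boundary-projected
  β_hmC = 0 cells must be pulled into the open interval for the beta
  likelihood; a clamp of 10⁻⁶ creates logit ≈ −13.8 leverage points that
  visibly inflate the false-positive rate on low-5hmC probes, while 10⁻³
  matches the practical resolution of array β values.
* Optimizer tolerance 10⁻⁸ (ftol), 500 iterations max; Hessian by central
  differences of the analytic gradient (step 10⁻⁵·max(1, |θ|)).
* Bounds: |b| ≤ 30, φ ∈ [0.5, 10⁶], σ_u ∈ [10⁻³, 10].
* Exactly-zero b3 is labeled toward_mC by convention and flagged.
* A fast fallback backend (`lmm_logit`: linear mixed model on logits,
  same design, via statsmodels MixedLM) is provided for screening and is
  labeled in its output; it is not the canonical model.

## Synthetic data

The generator emulates a paired EPIC-like experiment on neuron-enriched
postmortem cortex and keeps its ground truth for recovery tests.

* **Cohort**: ages N(79.3, 9.1²) control / N(79.4, 7.1²) disease clipped
  to [53, 93]; PMI N(3.25, 0.81²) / N(3.27, 0.83²) clipped to [1.8, 5.5]
  hours; glial proportion Beta(8, 15) (mean ≈ 0.35, so the 0.50 exclusion
  bites occasionally); male by default. Defaults are 29 control / 27
  disease samples.
* **Truth**: bimodal methylation m0 (35% Beta(1.5, 12), 65% Beta(10, 3));
  low-level hydroxymethylation h0 ~ Beta(3, 22) (mean ≈ 0.12 — 5hmC is a
  minor but prominent mark in neurons); pairs violating m0 + h0 ≤ 1 are
  jointly resampled. A fraction `prop_idmc` of probes (floor rule) receive
  a signed shift δ: disease means are m0 − δ, h0 + δ, so total
  modification is conserved exactly (pure-shift model; independent m/h
  changes available via `pure_shift: false`). Shifts are only placed where
  the simplex allows them; sign can be forced (`shift_direction`).
* **Measurement**: channel means are total modification (BS) and m only
  (oxBS); covariate effects (glial 0.5, PMI 0.05 per SD) act on the logit
  of each channel mean, centered so probe means stay at truth marginally.
  Observed β ~ Beta(μφ, (1−μ)φ) with φ_BS = 100, φ_oxBS = 60 — the oxBS
  chemistry is harsher, hence noisier — and failure rates 0.002 (BS) /
  0.02 (oxBS): failed entries draw detection p above 0.01 and missing β.
  Draws landing numerically on 0/1 are nudged into the open interval.
* **What it does not emulate**: probe type I/II chemistry, batch and chip
  effects, raw intensities, inter-individual biological variability of the
  methylome (per-group true levels are shared across samples apart from
  covariate effects), and spatial correlation along the genome. Passing
  tests therefore demonstrate calibration and power under measurement
  noise and covariate structure, not under biological heterogeneity;
  because the robust variance is agnostic to the correlation's sign, the
  inferential guarantees carry over, but empirical power on real data will
  differ.
* The manifest and chromatin-state generators scatter probes over two
  chromosomes with unique positions, mark ~5% of probes as masked, give
  ~65% of probes gene annotations (occasionally multi-gene or duplicated
  fields, to exercise de-duplication), and tile each chromosome with
  2 kb labeled state intervals.

## Annotation conventions

Manifest positions are 1-based coordinates of the interrogated cytosine;
chromatin states are 0-based half-open BED intervals. The single
conversion point maps probe position p to base p − 1 and tests containment
in [start, end). Overlapping intervals are resolved lexicographically by
(start, end, state) and logged. Gene fields split on ';' with per-probe
and global de-duplication, so the unique-gene count can exceed the genic
probe count; intergenic probes count toward total but not genic iDMCs.
GO/pathway enrichment and protein-network analysis are out of scope
(external curated databases); a plain one-symbol-per-line gene list is
exported for use with external tools.

## Problem sizes

The study-scale simulations used throughout (tests, analysis drivers,
acceptance script) are 2,000 probes × 56 samples — large enough that
Monte-Carlo standard errors on a 5% rate are ≈ 0.5% while a full
interaction scan stays under a minute — and 100 replicates at 500
samples/group for interval coverage. The per-fit cost is ~25 ms at n = 56
and ~0.3 s at n = 1,000.

## Known limitations

* The interaction model assumes a common precision φ across modalities;
  β_hmC is noisier than β_mC after deconvolution, which the robust
  variance absorbs for testing but which biases φ̂ toward a compromise.
* The random-intercept variance is weakly identified with two observations
  per sample and frequently collapses to its bound; σ̂_u should not be
  interpreted substantively at this design size.
* Boundary-projected β_hmC values make the outcome zero-inflated at
  low-5hmC probes; the low-level filter removes the worst cases, and the
  clamp bounds the leverage of the rest, but heavy zero-inflation beyond
  the simulated regimes would call for an explicit mixture likelihood.
* BH-FDR assumes the usual positive-dependence conditions; probes are
  simulated independently, while real neighboring CpGs are correlated.
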