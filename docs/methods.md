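# Methods

This note documents the statistical model, the simulators, the numerical
conventions and the open design choices behind `hybcal`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and measures

**Per-gene model.** For gene *g* the log2 expression level conditional on the
binary sample label *y* is Gaussian with class means μ_g,0, μ_g,1 and a
shared standard deviation σ_g. Fitting is pure maximum likelihood: class
means are sample means, the pooled variance uses denominator *N* (not
*N*−1), and σ_g is floored at `sigma_floor = 1e-6` so constant genes do not
produce infinities. The label prior P(y=1) is the training-fold frequency
(0.5 in the balanced designs this package requires).

**Dual representation.** Bayes' rule applied to the two Gaussians gives a
posterior that is exactly logistic in x, P(y=1|x) = σ(wx+b) with
w = (μ₁−μ₀)/σ² and b = (μ₀²−μ₁²)/(2σ²) + ln(P₁/(1−P₁)). The identity is
algebraic, and the test suite verifies it to 1e-10 against a direct
density-ratio computation over 10⁴ random models. Posteriors are clipped to
[ε, 1−ε] with ε = 1e-6 so that log scores stay finite.

**Protocol scores.** Two likelihoods are reported per protocol: the joint
Gaussian log-likelihood (intensity scale) and the naive-Bayes log-likelihood
Σ ln P(y_n|x_g,n) (label scale). The naive-Bayes form omits the
label-independent normalization constant; since protocols are only ever
*compared*, constants cancel and the reported quantity is ≤ 0. Likelihoods
are in nats; the mutual information is in bits (log base 2), matching its
interpretation as a bit rate. Which likelihood drives a ranking is
configurable; the rank-stability machinery uses the naive-Bayes form.

**Cross-testing.** Model-free diagnostics are estimated by N-fold
cross-testing whose folding unit is the *slide*: both channel-observations of
a slide stay in the same fold, preventing leakage between a slide's two
channels. "loo" puts one slide per fold. Held-out posteriors feed

* the generalization accuracy (percent correct at threshold 0.5; a posterior
  of exactly 0.5 predicts label 0, a deterministic tie-break that makes ties
  count as errors for label-1 observations);
* per-gene ROC curves by threshold enumeration with trapezoidal AUC. The
  averaged curve interpolates each gene's TPR on a fixed 101-point FPR grid
  and averages vertically; the summary AUC is the mean of per-gene AUCs.
  Pooling all genes' scores into one curve was rejected because per-gene
  posterior scales differ;
* the bit rate Î_g = (1/N) Σ_n log2 P(y_n|x_g,n)/P(y_n), averaged over
  genes. The finite-sample estimate is reported unclipped and can be
  slightly negative for uninformative genes.

A caveat the package documents deliberately: the held-out plug-in bit rate is
*systematically* negative under label independence (for any fitted posterior,
E_y log P̂(y|x) ≤ log 0.5 with equality only at P̂ = 0.5), so label-shuffle
controls should be read as "near zero, slightly below" rather than centred on
zero. At the typical 6-slide design the shuffle mean is around −0.2 bits;
this is cross-validation pessimism, not signal.

## Rank-stability validation

Genes are stratified into Z/L/M/H by quartiles of d_g = |μ₁−μ₀|/σ computed
on pooled data, ties broken by gene id so the assignment is deterministic.
Quartiles guarantee non-empty strata; at small replicate numbers the noisy
d_g statistic confuses some adjacent strata (~20% at 12 observations), which
is intrinsic to the statistic and shrinks with replication. Subsamples draw
stratum proportions from a flat Dirichlet(1,1,1,1), then sample genes without
replacement within strata (largest-remainder integer allocation; requests
exceeding a stratum are truncated). Default: 100 subsamples of G/4 genes.
Within one subsample, every protocol is scored on the *same* gene subset — a
paired comparison; otherwise subset noise would swamp protocol differences.
Exact score ties (identical input files) are broken by a per-subsample random
permutation so tied protocols share rank 1 evenly instead of the first
protocol winning every tie.

The recommendation rule: protocols whose rank-1 share is at least half the
maximum share are joint winners; among winners the highest hybridization
temperature is recommended (lower temperatures carry more
cross-hybridization potential). The result is flagged stable when the
winners' temperatures span at most 2 °C — a *temperature window* rather than
positional adjacency, chosen because adjacency in protocol order is
meaningless when only distant temperatures are tested; 2 °C covers the 1–2 °C
spacing of realistic calibration grids. Instability is additionally
diagnosed by the Shannon entropy of the rank-1 distribution (flag above 1.5
bits ≈ more than ~3 equally credible winners), which indicates that the
calibration samples themselves are unsuitable (e.g. biased towards one
regulation direction).

## Synthetic data

### Gaussian contamination study

`gaussian_group_dataset` plants 4×100 genes with log2 effects (0, 0.5, 1, 2)
for the Z/L/M/H groups, baselines N(8, 1.5), effect sign random per gene,
observation noise sd 0.3, and 6 dye-swap slides — a typical two-colour
calibration experiment. `apply_crosshyb_offset` adds 0.3 log2 units to the
lower-expression channel of a random half of each selected group's
weakly-expressed genes (bottom half by baseline). For the zero-DE group the
contaminated channel is drawn at random: a non-expressed gene has no true
lower channel, and using the *empirically* lower channel would make the
offset cancel the gene's own noise separation instead of creating spurious
signal. The study's qualitative outcome — Z-only contamination inflates the
naive-Bayes likelihood, contamination across all groups deflates it — is a
property of likelihoods: spurious separation of null genes adds a little,
lost separation of truly differential genes costs more.

### Langmuir chip simulator

Each probe binds its target with occupancy θ = cK(T)/(1+cK(T)) and binding
constant K(T) = exp(−ΔG(T)/(R·T)), ΔG(T) = ΔH − TΔS (R = 8.314×10⁻³
kJ/mol/K). Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| ΔH (target) | U(−350, −250) kJ/mol | duplex enthalpy; sets how fast binding weakens with T |
| ΔG at 324.15 K | U(−18, −12) kJ/mol | free energy at the 51 °C reference; the narrow window encodes a *well designed* probe set with similar binding strengths |
| cross-hyb fraction | 0.10 | probes with 1–12 non-targets |
| non-target ΔG | target ΔG × U(0.3, 0.7) | strictly weaker (less negative) binding at all simulated temperatures |
| amplitude α | U(0.02, 0.2) | cross-duplex signal scale relative to self binding |
| concentration | lognormal(ln 0.004, 1.0) | median probe near the isotherm midpoint at 51 °C |
| amplitude / background / noise | 1000 / 50 / 15 (a.u.) | intensity scale, additive floor and measurement noise |
| temperature grid | 45–60 °C, 3 °C steps | brackets the compromise optimum with clear contrasts |

Entropies follow from ΔS = (ΔH − ΔG_ref)/T_ref, which keeps target ΔG < 0 and
K(T) decreasing across the whole grid. Cross-hybridization is a sum of
independent amplitude-scaled Langmuir terms driven by the partner genes'
concentrations (no competitive depletion — competition adds parameters
without changing the qualitative optimum). Intensities are
amplitude·θ(target) + Σ α·θ(non-target) + background + Gaussian noise,
clipped at 1 and log2-transformed into a balanced dye-swap `ExpressionSet`.
Sample scenarios fix the Z/L/M/H fractions, per-stratum linear fold changes
(1, 1.5, 2, 4), a direction bias (share of DE genes down-regulated), and one
biological realization is reused across a temperature sweep so only the
hybridization physics and measurement noise differ between temperatures.

The simulated optimum emerges from two penalties: at high temperature
K collapses and differential signal drowns in the additive noise floor
(sensitivity loss); at low temperature probes saturate (θ → 1 compresses
fold changes) and cross-hybridization grows. A finding this package
documents rather than hides: in this model, cross-hybridization *inflates*
the training likelihood at low temperatures — contaminant signal is
reproducible across replicate slides and partner-driven differences look
like real signal, especially on dim probes — so heavy contamination biases
the apparent optimum *downwards* rather than penalizing low temperatures.
This is the same artefact the contamination study demonstrates on Gaussian
data, and it is the reason the recommendation rule resolves winner overlaps
towards the higher temperature.

### What the generators do not emulate

Real scanner artefacts (saturation clipping, spatial gradients), dye-specific
bias beyond what the dye swap cancels, probe-sequence-specific effects
(nearest-neighbour thermodynamics, secondary structure), correlated noise
between genes, and non-equilibrium hybridization kinetics. Passing tests
therefore demonstrate the *statistical machinery* under the stated physical
model, not platform-specific performance; real-platform numbers (score
tables, 90% rank-1 shares, thousands of significant genes) depend on real
calibration data and are not reproduced at this scale.

## Differential-expression impact

A balanced two-channel dye-swap design reduces exactly to one
orientation-corrected log ratio per slide (label-1 channel minus label-0
channel), and the per-gene balanced ANOVA with slide as block reduces to a
one-sample t test of that ratio against zero — full mixed-model machinery is
unnecessary for this design. p-values are two-sided with slides−1 degrees of
freedom; zero-variance genes get p = 0 if the mean ratio is non-zero else 1
(documented degenerate rule avoiding NaNs). Benjamini-Hochberg q-values use
the standard step-up (statsmodels); significance is *strict* q < 0.01 by
default. Protocol comparison partitions the optimal protocol's significant
set into retained and lost genes, summarizes |log2 FC| for both (five-number
summaries; box-plot data), and tests category enrichment in the lost set by
Fisher's exact test (two-sided by the minimum-likelihood convention; the
odds ratio is the sample odds ratio ad/bc, infinite when bc = 0 with ad > 0).
Whether a one- or two-sided test is used barely matters for clearly enriched
tables; two-sided is the conservative default.

## Numerical conventions and degenerate inputs

* log2 for expression values (raw intensities clipped at a configurable
  floor, default 1.0, before transform); natural log for likelihoods; log2
  for information.
* Population (1/n) standard deviation in scale normalization, consistent
  with the ML variance convention of the model fits.
* Zero-variance observation columns make location-scale normalization fail
  loudly, naming the column.
* All generators and procedures take an explicit numpy `Generator`; a fixed
  seed reproduces every output bit-for-bit.
* Stratification and subsampling tie-breaks are deterministic (gene-id
  order, stable sorts); only exact protocol-score ties are randomized, by
  design (see above).

## Problem sizes

Default study sizes — 400-gene contamination studies, 2000-probe chips, six
temperatures, five scenarios, 100 subsamples, 50-seed repetition — were
chosen so the full validation suite and the acceptance script each run in
well under a minute on one CPU while leaving the qualitative conclusions
unambiguous; all are parameters, and larger runs only sharpen the same
patterns.

## Known limitations

* Binary sample labels only; no multi-class designs or unbalanced-design
  reweighting beyond prior estimation.
* No moderated/shrinkage variance estimators; with few slides the per-gene t
  test is noisier than, e.g., an empirical-Bayes analysis would be.
* The held-out bit rate's negative null bias (above) means shuffle controls
  should not be tested against exact zero.
* The Langmuir simulator is an equilibrium, single-binding-site model with
  additive cross-hybridization; it is a validation instrument for the
  measures, not a quantitative model of any specific platform.
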