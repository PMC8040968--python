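# Methods

This note records the statistical models behind each analysis stage,
the parameters that matter, what the synthetic-data generators do and
do not emulate, and the numerical choices made where the design was
genuinely open.

## Equilibrium-dialysis interactomics statistics

### Model

Let A_p and A_m be the measured abundances of a metabolite in the
protein and metabolite chambers of one dialysis well. The per-replicate
signal is r = log₂(A_p/A_m): positive when the protein retains
(binds) the metabolite, negative when an active enzyme consumes it.
The observed matrix of collapsed fold changes decomposes as

    FC = E + Σ_f u_f v_fᵀ + ε

where E is the sparse matrix of true interaction effects, the low-rank
term captures pair-nonspecific systematic variation (chamber loading,
pool batch, injection drift — variation shared across metabolites
within a protein sample), and ε is replicate noise. The first three
principal components of the column-centred matrix are subtracted to
estimate and remove the systematic term; the fraction of variance
removed is reported, not asserted, because it depends on the screen's
composition.

### No-signal model and calibration

Each metabolite's null distribution is estimated from its own corrected
fold changes across all protein samples in the dataset, using
tail-insensitive statistics: centre = median, scale
σ = IQR / (2 Φ⁻¹(0.75)). True binders sit in the tails and barely
perturb either. Two refinements keep the null z-scores calibrated when
the protein panel is modest:

- **Quantile definition.** Sample quantiles use the normal-unbiased
  plotting positions (h = (n + ¼)p + ⅜). The default linear
  interpolation underestimates the IQR of a normal sample by ~7% at
  n = 20, which alone inflates all z-scores by ~1.07 and multiplies
  far-tail false positives several-fold.
- **Scale shrinkage.** The IQR-based σ̂ carries few effective degrees
  of freedom (the IQR estimator's efficiency is ≈0.37 per observation,
  so n = 20 samples give ≈7 effective df; relative SE ≈ 26%). Raw
  per-metabolite variances are therefore shrunk toward the pooled
  variance across metabolites:

      σ²_shrunk = (d₀·σ²_pool + d_eff·σ̂²) / (d₀ + d_eff)

  with prior df d₀ = 20 by default (`prior_df`, set 0 to disable).
  This is the standard empirical-Bayes variance moderation of
  small-sample screening statistics. Without it, measured false
  discovery among significant calls on the default synthetic screen is
  ~0.65–0.80 despite the nominal q < 0.1; with it, ~0.07–0.11.
  The prior df value trades robustness to genuine per-metabolite
  heteroscedasticity (large d₀ over-smooths) against calibration
  (small d₀ under-corrects); 20 gives the pooled estimate roughly
  three times the weight of a 20-sample raw estimate, appropriate when
  metabolite noise scales are similar after log transform.

p-values are two-sided normal tails — both enrichment and depletion are
reportable signals. Multiplicity is controlled with Storey q-values:
π₀(λ) = #{p > λ}/(m(1−λ)) on λ ∈ {0.05, …, 0.95}, smoothed by a cubic
least-squares fit and read off at λ = 0.95, clipped to (0, 1], with a
conservative π₀ = 1 fallback below 100 tests; q is the usual step-up
min_{j≥i} π₀ m p_(j)/j, which reduces exactly to Benjamini–Hochberg at
π₀ = 1. Significance requires p < 0.05 and q < 0.1 (strict).

### Outlier rule

Within an n = 3 triplicate the sample z-score is algebraically bounded
at 1.155, so a "z > 5" rule must reference a wider scale: the median of
all triplicate standard deviations in the dataset. At most the single
most extreme replicate per triplicate is masked, and never when only
two replicates remain.

## Thermal shift (DSF)

Two-state unfolding reported by an environment-sensitive dye:
F(T) = F_low + (F_high − F_low)/(1 + exp((Tm − T)/s)). Dye curves
decay after the fluorescence peak (dye release on aggregate
dissociation), so fitting uses points up to the global maximum only.
Initialisation — Tm at the maximal first derivative, s = 2 °C,
plateaus from the curve extremes — gives a robust least-squares basin;
a model-free derivative-maximum Tm is available as a cross-check.
ΔTm is measured against the mean of all vehicle wells. The hit
threshold defaults to 2 °C: several-fold above well-to-well Tm noise
(~0.3 °C) and below the weakest genuine stabilisers worth following up
(~3 °C). Multi-transition (two-domain) melts are out of scope.

## Dose–response

Four-parameter logistic in linear concentration,
Y = Bottom + (Top − Bottom)/(1 + (X/IC₅₀)^h), unweighted least squares
(1/Y² weighting optional), Hill slope bounded to (0.2, 5) to prevent
degenerate fits, Top free by default (a fixed-Top variant is provided).
Zero-dose anchors are exact in linear space; an optional log-space
parameterisation (optimising log₁₀ IC₅₀, pseudo-dose for zeros) agrees
with the linear fit on clean data and is sometimes better conditioned.
The inflection IC₅₀ is reported as K_i, matching the
inhibitor-vs-response convention; no Cheng–Prusoff correction is
applied because the assays are reported relative to an uninhibited
control rather than at varied substrate.

Partial inhibition is decided from the floor fraction f = Bottom/Top
with a delta-method SE from the fit covariance: *partial* if
f − 2SE > 0.10, *complete* if f + 2SE < 0.10, else *indeterminate*.
Curves whose activity span is below 30 percentage points are rejected
as uninformative (e.g. a co-ligand inert across the tested range), and
designs whose top dose is below ~10× the fitted IC₅₀ trigger an
identifiability warning for the floor.

## Steady-state SPR

1:1 Langmuir isotherm R_eq = R_max C/(K_d + C) by least squares on a
serial-dilution design (geometric series helper included). When the
top concentration is below K_d/2 the isotherm is nearly linear, K_d
and R_max become collinear, and a saturation warning is raised.
Replicates are summarised by geometric-mean K_d and fold-spread —
affinities live on a log scale, so no single replicate is promoted to
a headline value. Raw-sensorgram kinetics (k_on/k_off) are out of
scope; a plateau-averaging R_eq extractor is provided for convenience.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure each stage
assumes: triplicate log-ratio noise (default SD 0.3 log₂ units),
sparse true effects (default 5% of 400 metabolites at |log₂FC| = 2,
each paired with one protein of a 20-protein panel), rank-3 systematic
variation (outer-product factors, scale 0.5 log₂ units — the explicit
target of the PC-removal step), single-replicate multiplicative spikes
(1% of pairs — the target of the outlier rule), Boltzmann melts with
post-peak decay on a 25–95 °C grid, 4PL curves on an 11-point design
spanning 0.05–100 µM with a zero-dose anchor, and isotherms on the
eight-point 1:1 dilution from 6.25 µM. Scenario constants (thermal
shifts +3/+4/+7/+10 °C in a 162-compound library; K_i 5.8, 0.78, 4.2,
6.8 and 3.0 µM with 0/30/50% floors; replicate K_d pairs 596/612 nM,
1.47/1.175 µM, 1.057/4.3 µM) match the magnitudes of a real
regulatory-domain campaign so the recovery benchmarks are exercised at
realistic signal-to-noise.

Not emulated: mass-spectrometry ionisation and ion-suppression
physics, dialysis membrane kinetics, correlated (non-Gaussian)
instrument noise, plate-position effects beyond low-rank structure,
and compound-dependent assay interference. Passing benchmarks
therefore demonstrate correctness and calibration of the statistics
under the assumed error model, not robustness to every failure mode of
real instruments.

## Benchmark problem sizes

The self-benchmarks use 20 seeded screens for the interactomics error
rates and the thermal-shift hit accuracy, and 100 seeded curves for
each noisy-recovery estimate — enough to pin medians and proportions
to a few percent while keeping a full benchmark run around ten
seconds. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical seeds reproduce outputs
byte-for-byte, and the pipeline manifest records input/output sha256
hashes to verify it.

## Known limitations

- The no-signal model needs a panel of protein samples; with only a
  handful of columns the per-metabolite quantiles are dominated by the
  shrinkage prior, and with a single protein construct the population
  is degenerate by construction. Screens of one or two constructs
  should be analysed jointly with a larger reference panel.
- π₀ estimation is unstable below a few hundred tests; the
  conservative fallback (π₀ = 1) makes q-values coincide with BH there.
- The 4PL floor and Hill slope are weakly identified when the top dose
  is within a decade of IC₅₀; the module warns but cannot rescue such
  designs.
- Melt fitting assumes a single dominant transition; constructs with
  two well-separated melting domains need a mixture model.
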