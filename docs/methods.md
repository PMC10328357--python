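# Methods

## Problem and model

Charcoal retains a chemical imprint of the maximum temperature it reached
during charring. Mid-infrared (ATR-FTIR) absorbance spectra of charcoal
powder express this imprint as systematic changes in band intensities across
the 1800–400 cm⁻¹ fingerprint region: carbonyl and polysaccharide bands fade
with increasing temperature while condensed-aromatic bands grow. `charterm`
calibrates this relationship per wood taxon with a single-response partial
least squares (PLS1) regression,

    X (n × p spectra)  →  latent scores T = X·W  →  ŷ = T·q + ȳ,

where the weights `W`, loadings `P`, and y-loadings `q` are extracted by the
classical NIPALS deflation: per factor, `w ∝ Xᵀy` (unit norm), `t = Xw`,
`p = Xᵀt/(tᵀt)`, `q = yᵀt/(tᵀt)`, then `X ← X − tpᵀ`, `y ← y − qt`. New
spectra are scored by the same sequential deflation with the stored `W` and
`P`. Predictions are deliberately not clipped to the calibration range:
extrapolation beyond 600 °C is scientifically meaningful (hotter fires) and
is logged rather than censored.

The calibration design mirrors the laboratory reference sets: one composite
sample per charring step at 350–600 °C in 50 °C increments (n = 6 per taxon),
spectra resampled to 250 points on the descending 1800–400 cm⁻¹ grid
(spacing ≈ 5.62 cm⁻¹) by linear interpolation, without extrapolation.

## Preprocessing

Each spectrum is processed independently — Standard Normal Variate (SNV,
centre and scale to unit sample sd, n−1 denominator) to correct
multiplicative scatter, then a running median (default window 5 grid points,
nearest-value padding) for spike noise — before column mean-centering whose
constants come from the calibration set only and are replayed unchanged on
test spectra. The response is mean-centred alongside, giving an
intercept-free latent-variable fit; predictions add the calibration mean
back. The operation order (SNV → median filter → centering) follows the
conventional chemometric stack; the window of 5 points (~28 cm⁻¹) removes
1–2-point spikes without erasing diagnostic bands, which span several grid
points at 12 cm⁻¹ width.

A consequence worth knowing: SNV divides each spectrum by its own standard
deviation, which itself varies with temperature, so the preprocessed map
T → spectrum is a *ratio* of affine functions, not affine. Even with noise
switched off a 1-factor model is therefore only approximately exact after
SNV (within a few °C over the calibration range); exactness to 1e-6 °C holds
for the linear pipeline (SNV off, window 1), and the tests exercise both
regimes.

## Factor selection and validation

Leave-one-out cross-validation refits the *entire* pipeline — including the
centering constants — inside every fold, so held-out predictions never see
held-out statistics. The factor count F is chosen by minimising
`AIC = n·ln(RMSECV²) + 2·(F+1)` (the +1 counts the intercept), with ties
resolved toward fewer factors; leave-one-out is forced by n = 6. When a
fold's data support fewer factors than requested, the deepest achievable
model is used (an uninformative fold falls back to the training-fold mean,
which yields the closed-form RMSECV √10500 ≈ 102.47 °C on the 350–600 grid).
The reported r² is the squared Pearson correlation of held-out predicted vs
observed temperatures (the alternative 1 − SSE/SST definition is available
via `r2_mode="ss"`), with a two-sided t-test on n−2 df for its p-value.

Guarding against spurious fits, a permutation test reruns the full pipeline
(preprocessing refit, AIC factor selection, LOO CV) on uniformly shuffled
temperatures — n_perm = 199 by default, with replacement over the
permutation group, add-one p-value `(1 + #{null ≥ observed})/(n_perm + 1)`.
A calibration is accepted only if p < α (default 0.05); rejected models
refuse to predict unless forced. Because only 720 distinct orders exist at
n = 6, the identity order recurs in roughly one of eight 99-shuffle runs and
then contributes one tie, so the perfect-signal p-value is 1/(n_perm+1) in
most runs and occasionally one step larger.

## Variable importance and diagnostic bands

Per-wavenumber relevance is summarised by
`VIP_j = sqrt(p · Σ_f SS_f w_jf² / Σ_f SS_f)` with `SS_f = q_f²·tᵀt`;
`Σ_j VIP_j² = p` identically. Diagnostic bands are local maxima of the VIP
trace above 1.0, reported greedily from the strongest down with a minimum
separation (default 30 cm⁻¹), each position refined to the
baseline-subtracted centroid of the ±3 surrounding samples — the median
filter flattens peak tops into plateaus, so detection is plateau-aware and
quantisation is undone by the centroid. Two caveats are intrinsic rather
than numerical: bands closer together than roughly their own width cannot be
resolved individually, and the SNV renormalisation deterministically
displaces the apparent importance maximum around a *dominant* band cluster
(the renormalisation cancels part of the direct intensity change there).
Isolated temperature-sensitive bands are recovered to within one grid step;
overlapping ones only as a cluster.

## Group comparison

Group predictions (taxon × stratigraphic unit, any number of replicate
spectra) are summarised as mean/min/max, rounded half-away-from-zero only at
report time. Between-group structure uses the classical one-way ANOVA
decomposition and Tukey–Kramer all-pairs tests via the studentized-range
distribution (unequal group sizes supported). The compact letter display is
built from the maximal cliques of the non-significance graph — exact for the
small group counts here — so two groups share a letter precisely when their
adjusted p exceeds α; letters are ordered from the largest group mean.

## Assemblage quantification

Fragment counts per taxon and stratigraphic unit give relative frequencies
`%A(SU) = 100·N_A(SU)/N(SU)` and the ubiquity-corrected mean
`%U(A) = (Σ_SU %A(SU))/n_SU`, computed from **unrounded** per-SU percentages
with absent taxa contributing zero (this convention reproduces the published
table; the alternative, averaging the rounded per-SU cells, does not).
Minimum-taxa counts exclude indeterminate labels. All percentages print at
one decimal, ties away from zero.

## Synthetic data

The generator emulates the laboratory design, not pyrolysis chemistry: a
spectrum is a sum of Gaussian bands (σ = 12 cm⁻¹) on a gentle linear
baseline, with band amplitude `a_b(T) = base_b + slope_b·(T − 475)` —
temperature anchored at the 475 °C midpoint so slopes read as symmetric
deviations — times a per-spectrum log-normal scatter factor (sd 0.05), plus
i.i.d. Gaussian noise (sd 0.005 absorbance). Base amplitudes lie in 0.2–1.0
and sensitive slopes are ±4×10⁻⁴ absorbance/°C; all are invented fixture
constants pinned in tests. Per-taxon presets place the temperature-sensitive
bands at each taxon's diagnostic wavenumbers (olive: 1730, 1580, 1410, 800,
740; evergreen oak: 1580, 1410, 1370, 800, 740, with a temperature-neutral
1730; maritime pine: 1730, 1410, 1370, 1245, 1040) plus neutral filler bands
(1570, 1380, 1270, 1040) common to burnt organic matter. Slope signs follow
the chemistry: carbonyl/polysaccharide/resin bands decay with charring,
aromatic bands grow.

What passing tests on this generator do show: the pipeline recovers a linear
band-intensity–temperature relationship through realistic scatter and noise,
selects a parsimonious factor count, rejects shuffled calibrations, and
localises isolated informative bands. What they do not show: performance on
real charcoal, whose temperature response is nonlinear and saturating, whose
baselines drift non-linearly, and whose within-taxon biological variation
(moisture, resin content, anatomy) the generator omits entirely.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen to make
the statistical checks sharp but quick: 100 random 8×5 problems for oracle
equivalence, 50 random datasets for the Tukey reference comparison, 20 seeds
× 3 true temperatures × 5 replicates for parameter recovery, and 200 runs ×
99 permutations for the null-calibration study (the package default of 199
permutations is reserved for single calibrations). Floating tolerances: PLS
vs reference 1e-6, vs least squares 1e-8, score orthogonality 1e-8, VIP
identity 1e-6 relative. Degenerate inputs fail loudly: zero-variance spectra
(SNV), zero-variance responses, rank-deficient factor requests, all-zero
count tables, and zero within-group variance each raise a dedicated
exception naming the offending sample where possible.

## Known limitations

- The linear-in-T band model is the weakest link to reality; real charring
  responses saturate above ~500 °C.
- With n = 6 the permutation p-value granularity is coarse and the identity
  permutation recurs; exhaustive enumeration of all 720 orders would be
  sharper (not the default, to match standard Monte-Carlo practice).
- The AIC form `n·ln(MSE) + 2(F+1)` is one of several small-sample variants;
  the choice is pinned by tests and swappable in code.
- Compact-letter construction by maximal cliques is exponential in the group
  count; fine for ≤ ~15 groups, not meant for more.
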