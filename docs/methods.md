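# Methods

`megrest` re-implements, as a tested library, a resting-state MEG source-space
analysis chain: scalar minimum-variance beamforming, automatic epoch
selection, periodogram spectral features (relative band power and the
individual peak frequency), leakage-corrected amplitude-envelope connectivity
(AECc), covariate-adjusted group statistics with effect sizes and FDR
control, resting-state-network (RSN) aggregation, and partial least squares
correlation (PLSC) between brain and cognitive variables. Because no real
cohort is bundled, every stage is validated against synthetic recordings with
planted, recoverable ground truth. This note documents the models, the
numerical choices, and what the synthetic validation does and does not show.

## Frequency bands and spectral estimation

The analysis range 0.5–48 Hz is tiled by six bands: delta 0.5–4, theta 4–8,
alpha1 8–10, alpha2 10–13, beta 13–30, gamma 30–48 Hz. A periodogram bin on
a shared edge belongs to the band whose *upper* edge it is (intervals
`(lo, hi]`, with delta keeping its 0.5 Hz lower edge), so the bands tile the
range exactly and no bin is counted twice.

Per epoch (16384 samples; 13.1 s at the 1250 Hz acquisition rate) the PSD of
each region is the raw one-sided periodogram (rectangular window, constant
detrend). Band power is the Riemann sum Δf·ΣP over the bins assigned to the
band; total power is the sum over the six bands; relative band power (RBP)
is band/total. This rectangle rule — rather than a trapezoid with
interpolated band edges — was chosen because it makes the six bands an exact
partition (RBP rows sum to 1 to machine precision), preserves Parseval's
identity exactly, and assigns a bin-aligned pure tone at a band edge wholly
to one band. Averaging over the subject's 8 selected epochs supplies the
variance reduction that windowing would otherwise provide.

The individual peak frequency (IPF) is the argmax of the occipital-average
PSD restricted to 4–13 Hz, computed on the epoch-averaged PSD. When the
same quantity is needed for *single-epoch* quality screening, the
occipital-average periodogram is first smoothed with a 0.5 Hz moving
average: raw periodogram bins are exponentially distributed, and at
0.06–0.08 Hz resolution the bare single-epoch argmax is dominated by
single-bin noise. The subject-level estimate uses no smoothing. A peak on a
search boundary is returned with a warning.

## Band-pass filtering

One zero-phase FIR implementation serves the signal generator and the
connectivity stage, so the planted "in band" and the analysed "in band"
agree exactly. Filters are linear-phase least-squares designs
(`scipy.signal.firls`), applied forward and backward (net response
|H(f)|²). Three design details matter and were each fixed after measuring
the frequency responses:

* **Transitions are constrained linear ramps, 0.5 Hz wide.** Leaving the
  transition regions as "don't care" gaps lets the least-squares response
  bulge above unity just outside the passband; raised to the fourth power
  (two passes, power units) such bulges appear as sharp spurious spectral
  peaks. Explicit 0→1 ramps remove them. The ramp still carries real power
  (~tw/5 per side in |H|⁴ units), which bounds the spectral purity of any
  FIR-generated band component — with 0.5 Hz transitions, a pure alpha1
  component measures ≈ 0.87–0.97 in its own band, not 1.0.
* **Order = max(3·fs/f_lo, 3.3·fs/tw), capped at one third of the signal
  length.** The classic three-cycles heuristic alone under-resolves bands
  narrower than the filter's spectral resolution (10–25% passband error for
  alpha1/alpha2/gamma); the second term floors the resolution at the
  transition width. Measured two-pass passband ripple is < 0.35 dB and the
  stopband exceeds 30 dB one transition width beyond the edges for all six
  bands at both 1250 Hz and 250 Hz.
* **Windowed-sinc fallback for pathological designs.** The wide 0.5–48 Hz
  covariance window (beamformer) makes the least-squares system
  ill-conditioned at these orders; `design_bandpass` probes the solution
  (tap magnitudes, unit passband response) and falls back to a Hamming
  windowed-sinc there. The six analysis bands always use the least-squares
  design.

Edge transients: the two-pass filter corrupts one filter order of samples at
each end; the connectivity stage discards that many samples from each end of
every envelope before correlating.

## Synthetic data with planted truth

Each region's signal is a sum of independent band-limited Gaussian
components (FIR-filtered white noise, one per band), scaled to target
variances. Because the filter skirts leak a few percent of each component
into neighbouring bands, target *measured* fractions would be biased; the
generator therefore solves `target = Lᵀ v` for the component variances `v`,
where `L[c, b]` is the closed-form fraction of band-c filtered white noise
(power spectrum |H_c|⁴) that band-integrates into band b. With this
calibration, measured whole-brain band fractions match the planted profile
to within ±0.01 (tested at ±0.03, the Monte-Carlo tolerance at the
simulated durations).

Defaults are the study conditions this package targets: two groups (35
cognitively normal, 11 impaired), 80 regions, 5 minutes at 1250 Hz,
16384-sample epochs; group spectral profiles differing in theta (higher in
the impaired group) and beta (lower), occipital IPF 9.1 ± 0.8 Hz (CN)
versus 8.7 ± 0.3 Hz (CI). Tests and the acceptance script run scaled-down
cohorts (6–20 subjects, 6–10 regions, 250 Hz, 2–5 minutes) chosen so that
every recovery statistic is estimated with adequate Monte-Carlo precision
while the whole suite stays fast; the planted effect sizes, rates and noise
levels are unchanged by the rescaling.

Planted structure, each element recoverable from `SimTruth`:

* **Occipital alpha peak.** In occipital regions, 75% of the pooled alpha
  (alpha1+alpha2) power is concentrated in a narrowband (±0.5 Hz, 0.3 Hz
  transitions) component at the subject's planted IPF. The 75/25 split makes
  the peak unambiguous against the broadband floor at single-epoch
  resolution, which is what real occipital alpha looks like and what the
  epoch screening needs.
* **Envelope coupling.** A coupled pair shares slow positive envelopes
  `e = clip(1 + 0.45·g, 0.05, ∞)` where `(g_i, g_j)` are unit-variance
  Gaussian processes (≤ 0.4 Hz) correlated at the planted strength, so the
  planted envelope correlation is known in closed form (clipping affects
  < 1% of samples). The carriers are fixed-frequency cosines at *separated*
  in-band frequencies: a drifting carrier converts passband ripple into
  spurious envelope fluctuation, and two carriers too close in frequency
  beat slowly within an epoch, creating zero-lag correlation that the
  orthogonalization step would strip along with the shared envelope. Coupled
  regions express the rhythm at 12× the band's calibrated variance —
  without the boost, the region's own other-band skirt leakage dilutes the
  extracted envelope and attenuates the recovered correlation by tens of
  percent.
* **Leakage.** Instantaneous symmetric nearest-neighbour mixing
  `I + εM` (M has 1/2 on ring neighbours, zero diagonal) — zero-lag only,
  exactly the confound AECc removes.
* **Artifacts and drowsiness.** Artifact epochs receive ±8 robust-SD
  half-sine transients of 100 ms on three random regions; drowsy epochs have
  all occipital alpha amplitudes halved.
* **Cohort.** Cognitive scores are `intercept + slope × brain feature +
  Gaussian noise`; questionnaire responses are integers 1–5 per activity at
  ages {6, 12, 18, 40, current}, discretised from latent engagement levels;
  missingness is inserted completely at random at the configured rate with
  the mask recorded.

All randomness flows from one seed through `SeedSequence([seed, stage,
subject])`, so outputs are bit-reproducible and stages can be regenerated in
isolation.

What the generator does **not** emulate: 1/f background, non-Gaussian or
nonstationary rhythms, realistic volume-conduction geometry (mixing is a
ring, not a lead-field), phase coupling, or physiological artifact
morphologies. Passing tests therefore demonstrate that the pipeline's
estimators recover second-order planted structure under realistic SNR — not
that they are robust to everything real MEG contains.

## Beamformer

Scalar minimum-variance spatial filters: `w = C⁻¹l / (lᵀC⁻¹l)` per source,
with C the sensor covariance of the 0.5–48 Hz band-passed recording and l
the (given, fixed-orientation) lead-field column. C is regularised as
`C + λ·mean(diag C)·I` with λ = 0.05 by default — the source never states a
regulariser, but finite recordings need one; λ is a fraction of the mean
sensor power, so the choice is scale-free. Unit gain (`w·l = 1`) holds by
construction and is verified to 1e-9. No head model, orientation search or
depth normalisation is included: lead fields are inputs.

## Epoch selection

Recordings are cut into consecutive non-overlapping 16384-sample candidates
(remainder discarded). Screening (thresholds chosen here; the original
study's exact values are not public):

* amplitude: any sample beyond 6 robust-z units (per-region median/MAD of
  the whole recording) — scale-free, catches the ±8 SD planted transients
  with margin;
* IPF outlier: epoch peak frequency outside median ± 3·MAD of the subject's
  candidates (robust at ~20 candidates);
* low alpha: occipital alpha1 RBP in the subject's lowest quartile — a
  relative, within-subject drowsiness screen. Because a quartile rule always
  removes ~25%, it is soft: if it would leave fewer epochs than requested,
  the best of the epochs it removed are restored (absolute rejections never
  are).

Survivors are ranked by the equal-weight rank-sum of epoch peak frequency
and occipital alpha1 power; the top 8 are kept, ties broken toward the
earlier start index, output in chronological order. Fewer than 8 usable
epochs raises an explicit subject-exclusion error. On 50 synthetic subjects
with 10% artifact and 10% drowsy epochs, 100% of selected epochs are
planted-clean.

## Connectivity (AECc)

Per epoch and band: band-pass filter; for each ordered pair, orthogonalize
the real signals in time (`y − (⟨y,x⟩/⟨x,x⟩)x`, removing the zero-lag
component); Hilbert envelopes; Pearson correlation; average the two
directions; symmetrize by averaging upper and lower triangles; average over
the 8 epochs. Implementation exploits linearity of the analytic transform —
`env(y − βx) = |A(y) − βA(x)|` — so each reference region costs O(R·T)
instead of one Hilbert transform per pair; a brute-force per-pair
reimplementation agrees to 1e-10. Degenerate (collinear) directions score
0: a pure zero-lag pair carries no corrected connectivity. Envelopes are
correlated raw (no low-pass, no downsampling, no log). Whole-brain
connectivity is the mean over the R(R−1)/2 distinct pairs; nodal strength
is the off-diagonal row sum.

Validation: AECc is exactly 0 for `y = αx`; planted envelope correlations
are recovered within ±0.03 at strength 0.6 (tolerance ±0.1), measured
against the planted modulators correlated over the same trimmed epoch
support the estimator uses; adding instantaneous mixing ε ≤ 0.3 moves AECc
by < 0.01 (tolerance ±0.05) while uncorrected AEC inflates neighbour
connectivity by > 0.05; whole-pair AECc is monotone in planted strength
over {0, 0.3, 0.6, 0.9}.

## Group statistics

Group differences use the nested-model F test: `y ~ 1 + covariates + group`
versus `y ~ 1 + covariates` (OLS via statsmodels), `F = (RSS_r − RSS_f) /
(RSS_f / (n − k − 2))` with p from F(1, n−k−2); this equals the squared t
of the group coefficient. Age and gender (binary indicator, reference F)
are the default covariates; RBP can be added when testing connectivity. The
pipeline drops a covariate that is collinear with the design (logged) —
with 11 subjects in the smaller group, a gender draw can coincide exactly
with the group split. Effect size is Cohen's d between the groups'
residuals from the covariate-only model, pooled SD with (n₁−1, n₂−1)
weights, sign = first-listed group minus second (CN − CI by default,
recorded in the result). Calibration at n = 35/11: type-I error 0.041–0.047
per 1000 null runs; mean recovered d = 1.14 for a planted 1.15 over 500
runs; rejection rate for a unit shift matches the closed-form noncentral-F
power (0.807).

Benjamini–Hochberg step-up is implemented from the definition (largest k
with p(k) ≤ k·q/m) and verified identical to a brute-force scan and to
statsmodels on 1000 random vectors; adjusted p-values are the standard
step-up minima capped at 1. Empirical FDR in a 60-feature mixed-signal
simulation is ≈ 0.035 at q = 0.05.

Spearman grids use midranks, the t approximation for p, pairwise deletion
(≥ 4 complete pairs per cell), and BH-FDR over the distinct off-diagonal
pairs; constant variables flag their cells NaN. RSN membership is assigned
by majority vote over a supplied region × network count table, exact ties
breaking by the fixed order VIS < SM < DA < VA < FP < DMN < LIM (flagged).
Per-network effect contributions are Σ|d| over significant member regions
divided by Σ|d| over all significant regions, × 100; |d| keeps the statistic
well-defined when a map mixes signs, and the output is invariant to uniform
rescaling of d. The questionnaire composites average the 1–5 responses at
the current age (cCAQ) and across ages 6, 12, 18 and 40 (pCAQ), excluding
missing items and recording the contributing counts.

## PLSC

Both blocks are column-wise z-scored (the blocks mix units — Hz, points,
years — and loadings are defined as correlations), so the decomposed matrix
`R = XᵀY/(n−1)` is the cross-block correlation matrix; `R = U S Vᵀ` gives
paired orthonormal saliences, latent scores `XU`, `YV`, loadings as
correlations of raw columns with own-block scores, and r² per component as
the squared correlation of the paired score vectors. `Σ s²` equals `‖R‖²_F`
(verified to 1e-9); sign flips of salience pairs change nothing observable.

Permutation test: rows of Y permuted, rank-matched singular values (no
Procrustes rotation — the simplest defensible statistic),
`p = (1 + #{s* ≥ s}) / (1 + N)` with N = 1000 by default, BH-FDR across
components. Under independence the first-component p-value is uniform
(KS p ≈ 0.45 over 200 replicates).

Bootstrap: paired rows resampled with replacement (500 by default); each
resample's components re-aligned to the original by greedy maximal
|salience inner product| (strongest original components choose first) and
sign-matched; the bootstrap ratio is the original loading over the bootstrap
SD of that loading, capped at ±1e3 when the SD is numerically zero (the
noiseless limit); |z| > 3 marks a reliable loading. Resamples with a
constant column are skipped and counted. With one active (r = 0.6) and one
inert cognitive variable at n = 100, the active one is reliable and the
inert one not in ≥ 90% of runs.

Missing cognitive entries are completed once, before PLSC (not re-imputed
within resamples), by 4-nearest-neighbour imputation: Euclidean distance
over z-scored mutually observed variables, rescaled by the fraction
observed, deterministic row-order tie-break; a missing cell becomes the
mean of the k nearest donors observing that variable.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → (beamform when sensor data + lead
field are supplied) → epoch selection → spectral + connectivity → group
statistics + RSN contributions + Spearman grid → PLSC (spectral and
connectivity brain blocks), persisting each product as CSV/TSV/JSON/HDF5
with every file name carrying the config hash. One global seed fans out via
`SeedSequence` stage tags; identical config + inputs + seed reproduce the
bundle exactly (tested on the permutation p-values and the full group-test
table). The bundled demo configuration (10–12 subjects, 10–12 regions,
250 Hz, 2 minutes, one coupled pair) runs end-to-end in well under a minute
on one CPU; full-scale cohorts scale linearly in subjects and quadratically
in regions for the connectivity stage.

## Known limitations

* Spectral purity of FIR band components is bounded by the transition
  ramps; single-band RBP saturates near 0.9, not 1.
* The epoch screen's thresholds (|z| > 6, ±3 MAD, lowest quartile) are this
  package's operationalisation of qualitative criteria; real pipelines tune
  them per study.
* The AECc envelope-recovery guarantee holds for rhythms that dominate
  their band (the planted regime); weak coupled rhythms are attenuated by
  within-band noise, a property of envelope correlation itself.
* PLSC inference assumes exchangeable rows under the null; the permutation
  scheme does not preserve group structure.
* The generator's leakage operator is a ring, so beamformer tests validate
  algebra and SNR behaviour, not anatomical localisation accuracy.
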