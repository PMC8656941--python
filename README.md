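# megrest

Source-space resting-state MEG analysis for small clinical cohorts:
spectral features, leakage-corrected envelope connectivity,
covariate-adjusted group statistics, and multivariate brain–cognition
association — with a synthetic test bench that plants recoverable ground
truth at every stage.

## Who this is for

Electrophysiology groups comparing patient and control groups on
resting-state MEG/EEG (for example cognitively impaired versus normal
oldest-old adults) who need the full chain from source time-series to
statistics as reusable, tested code rather than a one-off script stack:

* **Beamforming** — scalar minimum-variance spatial filters
  `w = C⁻¹l / (lᵀC⁻¹l)` from the broadband (0.5–48 Hz) sensor covariance
  and given lead fields, with exact unit gain at each source.
* **Epoch selection** — 16384-sample (13.1 s at 1250 Hz) candidate epochs
  screened for amplitude artifacts, peak-frequency outliers and low
  occipital alpha (drowsiness), then the 8 best selected per subject.
* **Spectral features** — periodogram PSD per region; relative band power
  (RBP) in delta 0.5–4, theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30
  and gamma 30–48 Hz (band integral / total power, rows summing to 1); the
  individual peak frequency (IPF), the 4–13 Hz argmax of the
  occipital-average PSD.
* **Connectivity (AECc)** — per band and epoch, signals are pairwise
  orthogonalized in time (removing zero-lag leakage), Hilbert envelopes are
  Pearson-correlated in both directions and averaged, matrices symmetrized
  and epoch-averaged; whole-brain means and nodal strengths.
* **Group statistics** — ANCOVA via nested-model F tests with age/gender
  covariates; Cohen's d between covariate-adjusted residual distributions;
  Benjamini–Hochberg FDR; Spearman grids with pairwise deletion; majority
  vote of regions onto the seven canonical resting-state networks and
  per-network effect-size contributions; cognitive-activity questionnaire
  composites (current cCAQ, past pCAQ over ages 6/12/18/40).
* **PLSC** — SVD of the cross-block correlation matrix `XᵀY/(n−1)` between
  brain features and cognitive scores: paired saliences, loadings,
  permutation p-values (1000 permutations, FDR over components), bootstrap
  reliability ratios (500 resamples, |z| > 3), and 4-nearest-neighbour
  imputation of missing cognitive scores.

Because raw clinical MEG is rarely shareable, the `synthdata` module is a
first-class citizen: it generates cohorts of source recordings with planted
band-power profiles, occipital alpha peaks, envelope-coupled region pairs,
instantaneous mixing (leakage), artifact and drowsy epochs, and cohort
tables whose cognitive scores depend linearly on brain features — all
recoverable from a `SimTruth` object, so every pipeline stage is testable
end to end. See `docs/methods.md` for the models and numerical choices.

## Worked example

Run the whole pipeline on a small synthetic cohort (8 controls, 4 impaired,
12 regions, 2-minute recordings at 250 Hz, one planted alpha2-coupled pair,
20% leakage mixing):

```python
from megrest import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=42, epoch_len=2048, n_epochs=8,
    connectivity_bands=("alpha2",), n_perm=500, n_boot=200,
    sim=dict(
        n_subjects_per_group={"CN": 8, "CI": 4}, n_regions=12, fs=250.0,
        duration=120.0, epoch_len=2048, occipital_idx=(0, 1, 2),
        coupling_pairs=[dict(i=4, j=8, strength=0.6, band="alpha2")],
        mixing_strength=0.2, artifact_rate=0.05, drowsy_rate=0.05, seed=42,
    ),
)
bundle = run_pipeline(cfg)
print(bundle.group_tests.set_index("feature").round(4)
      [["F", "p", "d", "p_adj", "significant"]])
```

which prints (about 10 s on one CPU):

```
                     F       p       d   p_adj  significant
feature
delta_rbp     122.2339  0.0000 -2.0552  0.0000         True
theta_rbp     371.7215  0.0000 -2.1517  0.0000         True
alpha1_rbp      2.1188  0.1836  0.7089  0.2761        False
alpha2_rbp      2.9672  0.1233  0.8221  0.2465        False
beta_rbp     3087.2654  0.0000  2.1977  0.0000         True
gamma_rbp       0.0000  0.9987  0.0009  0.9987        False
ipf             1.8842  0.2071  0.6724  0.2761        False
alpha2_aecc     0.3808  0.5543 -0.3141  0.6335        False
```

The planted group contrast is recovered with the right signs: the impaired
group has higher theta and lower beta RBP (d is CN − CI, so theta is
negative and beta positive), both surviving FDR, while bands planted with
near-identical fractions do not. `bundle.ipf` holds per-subject peak
frequencies (mean 8.86 Hz here, matching the planted 8.7–9.1 Hz range),
`bundle.plsc["spectral"]` the 7-component PLSC of spectral features against
cognition (7 brain features × 8 cognitive variables), and
`bundle.conn_matrices` the per-subject AECc matrices.

The same stages are available as a CLI:

```bash
megrest simulate --config config.json --out out/
megrest epochs --recordings out/recordings.h5 --config config.json --out out/
megrest run --config config.json --seed 1 --out results/
```

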