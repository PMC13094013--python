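# Methods

This note documents the models, parameter choices and numerical decisions
behind `chp_elastic`, and what the simulations do and do not establish.

## Signal model

Every tissue class is a mixture of compartments with spoiled gradient-echo
steady-state signals

S = M0 · sin α · (1 − E1) / (1 − cos α · E1) · exp(−TE/T2\*),  E1 = exp(−TR/T1),

assuming ideal spoiling and no inflow enhancement. The default compartment
table (3T-flavored design values, not fitted constants):

| compartment | T1 (ms) | T2\* (ms) | M0 |
|---|---|---|---|
| blood | 1650 | 50 | 1.25 |
| stroma | 3500 | 300 | 1.00 |
| ventricular CSF | 4000 | 500 | 1.00 |
| gray matter | 1300 | 45 | 0.78 |
| white matter | 850 | 45 | 0.74 |
| ChP epithelium | 1400 | 60 | 0.80 |

The table preserves the physiological ordering that matters — stroma
(plasma-like, no red cells) relaxes far more slowly than whole blood — while
using T2\* rather than T2 values appropriate for gradient-echo EPI. Blood's
M0 = 1.25 is an *effective* amplitude, not a proton density: it absorbs the
steady-state inflow enhancement of flowing spins that the SPGR equation
otherwise ignores, and is chosen so the blood/stroma signal crossover falls at
TE\* ≈ 35 ms at TR 2470 ms / 78° — between echoes 2 and 3 of the four-echo
protocol, so the simulated ChP response is positive at TE 12/28 ms and
negative at TE 44/60 ms. White/gray M0 values place the CSF/tissue contrast
ratio below 1 at TE 12 ms and above 1 for TE ≥ 25 ms at long TR, the
empirical gate for elasticity sensitivity. One consequence of a single global
TE\* is that the simulated ChP response at TR 2000 ms / TE 25 ms is mildly
*positive*; real cohorts show negative responses there, which suggests
tissue-specific T2\* spectra (or intravoxel CSF pulsation) that this
four-parameter-per-compartment table does not capture. Analyses meant to
exhibit the negative response therefore use TE 60 ms phantoms.

## ChP elasticity mechanism

A ChP voxel has baseline fractions f_blood0 = 0.15, f_stroma0 = 0.35,
f_csf = 0.30, remainder 0.20 static epithelium/other. Vasodilation exchanges
blood for stroma reciprocally:

f_blood(t) = f_blood0 + ε·ΔEtCO2(t),  f_stroma(t) = f_stroma0 − ε·ΔEtCO2(t),

so the total is conserved exactly (identical floating-point arithmetic on both
fractions). ε defaults to 0.005 per mmHg — a 4% blood-volume-fraction swing
over an 8 mmHg hypercapnic step, giving ChP percent responses of order
−0.17 %ΔBOLD/mmHg at TE 60 ms: small against parenchymal CVR, as observed in
practice. The signal change ΔS = ε·ΔC·(S_blood − S_stroma) is independent of
f_csf; raising f_csf only raises the baseline (CSF is brighter than what it
displaces), which *dilutes the percent change* — the partial-volume caveat for
interpreting percent-units elasticity in large ventricles. A trajectory that
would push any fraction outside [0, 1] raises an error naming the time point
rather than clipping silently.

Excursions enter relative to the *run-mean* EtCO2. This makes the voxel's
temporal mean equal its baseline signal exactly, so the percent-normalized GLM
recovers the constructed CVR to machine precision on noiseless phantoms — a
deliberate property used by the recovery tests; with a non-centered drive the
normalization would be biased by the mean excursion (≈0.8% at default
settings), which is within the measurement noise of any real run.

## Physiological traces

All paradigms produce a breath-by-breath capnograph waveform: inspiration at
~2 mmHg, half-cosine rise, expiratory plateau at the end-tidal envelope, with
0.3 mmHg per-breath plateau jitter and a 4 s breath period.

- **Hypercapnia**: room air / CO2 blocks alternating every 60 s for 7 min,
  envelope following the block design through a first-order wash-in
  (τ = 10 s — physiological rather than instantaneous, which also makes delay
  estimation non-trivial). The evoked step is +8 mmHg by default. The
  *recorded* trace lags the physiological drive by a configurable delay
  (sampling line + lung-to-brain transit), which the pipeline must recover.
- **Breath modulation**: seven 12 s paced epochs (3 × 2 s in / 2 s out)
  separated by free-breathing gaps drawn uniformly from 30–60 s (gap vectors
  are redrawn until the schedule fits the run; infeasible configurations
  error). Each epoch dips EtCO2 by −4 mmHg with a 4 s onset and 15 s recovery
  time constant.
- **Resting**: the envelope is Gaussian noise strictly band-limited to
  0–0.05 Hz (constructed in the frequency domain), SD 1.5 mmHg.

End-tidal extraction is peak detection: local maxima separated by ≥ 2 s with
prominence ≥ 25% of the trace's dynamic range, linearly interpolated onto
volume times. Synchronization scans delays over [−5, +30] s in 0.5 s steps
(covering transit plus line delay) and minimizes the residual sum of squares
of the whole-brain BOLD course regressed on the shifted EtCO2; the fit is
flagged if the optimum sits on the search boundary.

## Phantom and cohort

The default grid is 32×32×16 at 3 mm isotropic: a gray-matter head ellipsoid,
white-matter core, two ellipsoidal lateral ventricles and 2–3-voxel-thick ChP
strips on their medial walls (168 ChP voxels — comfortably above the 50-voxel
cluster-extent threshold). Gray/white matter carries a conventional
multiplicative BOLD response (0.20 / 0.10 %ΔBOLD per mmHg about the run-mean
drive); ventricular CSF is static; noise is additive white Gaussian at 0.2%
of the mean parenchymal signal, without temporal autocorrelation, so GLM
inference is exact by construction. Simulated cohorts draw each subject's ε
multiplicatively around the group value (CV 0.3, truncated at 0.2×), ages
from disjoint ranges (young 20–35, old 55–80), alternating sex, and an
individual capnograph delay (uniform 2–10 s under hypercapnia). The old
group's ε defaults to one third of the young group's.

What the phantom does *not* emulate: head motion, cardiac/respiratory
aliasing, field inhomogeneity and dropout, slice timing, temporally
autocorrelated noise, subject-specific anatomy or registration error. Passing
tests therefore demonstrate estimator correctness and the TE-dependence logic
of the mechanism, not robustness to real-world artifacts.

## Analysis defaults and numerics

- Spatial smoothing: Gaussian, FWHM 4 mm (σ = FWHM/√(8 ln 2) per axis in
  voxel units; anisotropic voxels honored). FWHM 0 is the identity.
- Absolute CVR: OLS per voxel of y on [1, EtCO2, t]; CVR = 100·β₁/ȳ with ȳ
  the voxel temporal mean — robust to drift and equivalent to the intercept
  normalization for demeaned regressors. The EtCO2 regressor is not demeaned
  (β₁ is unaffected). Voxels with ȳ below 5% of the mask mean are excluded
  (division guard).
- Global-signal regressor: mask-mean course, linear detrend, order-2
  Butterworth low-pass at 0.1164 Hz applied forward–backward (zero phase).
- Relative CVR: percent coefficients normalized by their mask mean, giving
  mask-mean exactly 1. A non-positive normalizer is flagged and the
  unnormalized percent map returned instead of raising.
- Group stage: one-sided voxel-wise tests in the direction of interest
  (negative for elasticity detection, positive for age attenuation);
  uncorrected p < 0.005 with cluster extent > 50 voxels, 26-connectivity by
  default (configurable to 6). Zero-variance voxels get t = 0 with a flag.
  ROI regressions use statsmodels OLS with normal-theory CIs; the ROI is
  defined from the group map and then applied per subject, inheriting the
  usual circularity of that design (documented, not corrected).
- All voxel-wise fits use `numpy.linalg.lstsq` on the stacked design; the
  test suite cross-checks them against independently coded normal-equation
  and scipy.stats oracles at 1e-8 relative tolerance.
- Determinism: every stochastic component takes a seed; identical seeds give
  bit-identical traces, phantoms and pipeline outputs.

## Problem sizes

Simulation studies in the tests and the acceptance script use the 32×32×16
phantom with 200–270 volumes per run, 20 replicate runs for delay recovery
and detection studies, 10 for noisy CVR recovery, and 20 replicates per arm
(17 young vs 10 old subjects) for the group-difference power and
false-positive-rate estimates — desk-scale sizes chosen so the full battery
runs in minutes on one CPU while keeping every inferential step identical to
the full-size analysis.

## Known limitations

- The compartment table is a design choice: absolute CVR magnitudes and the
  precise TE\* are illustrative, and only their orderings and signs should be
  compared against real data.
- Relative (r.u.) values depend on the phantom's parenchymal CVR mix through
  the whole-brain normalizer; they are larger in magnitude than typical
  cohort values.
- A single global capnograph delay per run; voxel-wise delays are not
  modeled or estimated.
- No registration: cohort subjects share one grid, so group analyses test
  statistics, not spatial normalization.
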