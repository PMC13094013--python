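# chp-elastic

Choroid-plexus (ChP) vascular elasticity mapping from BOLD fMRI.

The choroid plexus — the ventricular tissue that produces cerebrospinal fluid —
is supplied by fenestrated capillaries embedded in a plasma-like stroma. When a
vasoactive stimulus (CO2 inhalation, breath modulation, or spontaneous
resting-state fluctuation) dilates those capillaries, blood volume grows at the
expense of stroma volume inside each imaging voxel. Because stroma is MR-bright
(long T2*, like plasma: ~410 ms T2 at 3T versus ~100 ms for whole blood) and
blood is dark at sufficient T2* weighting, the exchange *lowers* the voxel
signal: a **negative cerebrovascular reactivity (CVR)** confined to the
ventricles, whose magnitude indexes the elasticity of the ChP vessel walls.
This package implements that measurement end to end, together with a
biophysical phantom simulator so every stage can be verified against ground
truth — useful for methods development, power analysis and teaching, since the
signal is small and cohort MRI data are expensive.

## The model

A ChP voxel is a mixture of compartments with volume fractions that respond to
end-tidal CO2 (EtCO2, the per-breath expiratory plateau, a proxy for arterial
CO2):

```
f_blood(t)  = f_blood0  + ε · (EtCO2(t) − EtCO2_baseline)
f_stroma(t) = f_stroma0 − ε · (EtCO2(t) − EtCO2_baseline)        (reciprocal)
S(t) = f_blood·S_blood + f_stroma·S_stroma + f_csf·S_csf + f_rest·S_epi
```

where each compartment signal follows the spoiled gradient-echo steady state
`S = M0 sin α (1 − E1)/(1 − cos α · E1) · exp(−TE/T2*)`, `E1 = exp(−TR/T1)`.
The signal change for a CO2 excursion ΔC is `ΔS = ε·ΔC·(S_blood − S_stroma)`:
negative exactly when stroma outshines blood, i.e. beyond a crossover echo
time TE\* (≈35 ms at TR 2470 ms with the default tissue table). ε (blood
fraction per mmHg) is the elasticity parameter.

CVR estimation:

- **absolute** (`fit_cvr_glm`) — voxel-wise OLS of the BOLD course on the
  synchronized EtCO2 regressor plus a linear trend; maps in %ΔBOLD/mmHg. The
  capnograph trace is reduced to breath-wise end-tidal samples and aligned by
  a residual-minimizing delay search against the whole-brain signal.
- **relative / gas-free** (`fit_relative_cvr`) — voxel-wise OLS on the
  detrended, low-pass (0.1164 Hz Butterworth) whole-brain mean signal,
  normalized by the whole-brain mean coefficient (relative units, mean 1).

Group stage: voxel-wise one-sample t (direction negative) and age-regression
maps with uncorrected p < 0.005 and cluster extent > 50 voxels; ROI values
from the surviving clusters enter OLS regressions on age or group with sex as
covariate. A CSF/tissue contrast ratio (ventricle mean over periventricular
shell mean) gates sensitivity: the method only works where ventricles are
brighter than tissue (ratio > 1).

## Worked example

`examples/04_aging_cohort_group_stats.py` simulates 8 young + 8 old subjects
(old ChP elasticity set to one third of young), runs the full hypercapnia
pipeline per subject and the group analysis:

```
subjects analyzed      : 16 (0 failed)
negative clusters      : [124, 124] voxels
ROI size               : 248 voxels
ROI CVR, young         : -0.072 %dBOLD/mmHg
ROI CVR, old           : -0.023 %dBOLD/mmHg
group contrast (old-yg): +0.049, p = 1.57e-03
age slope              : +0.00127 per year, p = 2.04e-03
```

The two 124-voxel clusters are the ChP strips on the medial ventricle walls.
Old subjects' ROI means are less negative (stiffer vessels), and the positive
age slope quantifies the attenuation per year. The other examples cover
single-subject hypercapnia mapping (`01`), gas-free relative CVR (`02`), and
the echo-time dependence in multi-echo resting data (`03`), where the ChP
response flips from positive to negative between TE 28 and 44 ms while the
CSF/tissue contrast climbs from 0.98 to 2.41.

A thin CLI mirrors the pipeline stages:

```bash
chp-elastic simulate --paradigm hypercapnia --echoes 60 --delay 6 --seed 1 --out sim/
chp-elastic cvr --bold sim/bold_te60.nii.gz --etco2 sim/physio.tsv --out maps/
chp-elastic contrast --bold sim/bold_te60.nii.gz --csf-mask sim/ventricle_mask.nii.gz
```

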