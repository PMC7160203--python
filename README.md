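# boldvar

Frequency-specific analysis of resting-state BOLD signal variability for
studies of the Alzheimer's disease spectrum (healthy controls, amnestic
mild cognitive impairment, dementia), built as a fully testable pipeline
driven by a synthetic 4D fMRI phantom.

## The statistic

Moment-to-moment BOLD fluctuation amplitude is quantified as the temporal
standard deviation of the band-filtered signal at each voxel. For the
canonical low-frequency bands slow4 (0.027–0.073 Hz) and slow5
(0.01–0.027 Hz), the **fractional SD** is

    fSD_band(v) = SD_band(v) / SD_whole(v)

— the band's share of total fluctuation at voxel *v* — and the **z-fSD**
map standardises fSD spatially across in-brain voxels within each subject.
All temporal filters are zero-phase DFT brick-wall filters, so band
supports are exact and `Σ_band var = var_total` holds to numerical
precision.

Downstream, z-fSD maps are compared across diagnostic groups with a
voxelwise one-way ANCOVA (covariates: age, sex, education, total
grey-matter volume), cluster-level family-wise error controlled by
Freedman–Lane permutation of the maximum supra-threshold cluster, and
cluster ROI means are partially correlated with baseline cognition,
hippocampal volume and two-year cognitive decline in patients, Bonferroni
corrected per band.

Two preprocessing arms are implemented end to end:

* **GSR arm** — drop initial volumes, despike (robust-z winsorising),
  grand-mean scaling, 6-mm FWHM spatial smoothing, detrending, and
  nuisance regression (6 motion parameters, CSF, WM, whole-brain global
  signal).
* **ICA arm** — per-subject spatial ICA, five-feature noise scoring of
  each component (spikiness, brain-edge fraction, non-grey energy,
  high-frequency power, spatial roughness), rejection threshold chosen on
  a labelled training set by maximising the balance ratio
  `(3·TPR + TNR)/4`, and non-aggressive removal of flagged components.

## Worked example

```python
import numpy as np
from boldvar.synthdata import PhantomConfig, simulate_cohort
from boldvar.preprocess import smooth_gaussian
from boldvar.variability import compute_zfsd
from boldvar.groupstats import GLMDesign, permutation_cluster_fwe, label_clusters

eff = {("aMCI", "dmn_posterior", "slow5"): 1.5, ("aMCI", "sn", "slow5"): 0.67}
cfg = PhantomConfig(seed=3, effect_table=eff)       # 12 HC / 12 aMCI / 12 AD
runs, table, masks = simulate_cohort(cfg)

maps = [compute_zfsd(smooth_gaussian(r, 6.0))["slow5"].zfsd for r in runs]
mask = np.all([np.isfinite(m) for m in maps], axis=0)
stack = np.stack([m[mask] for m in maps])
design = GLMDesign.from_records(table)

clusters = permutation_cluster_fwe(stack, design, ("aMCI", "HC"), mask,
                                   n_perm=500, seed=0)
label_clusters([c for c in clusters if c.p_cluster_fwe <= 0.05], masks)
for c in clusters[:2]:
    print(c.size_k, round(c.peak_stat, 2), c.p_cluster_fwe, c.dominant_network)
```

prints (seed 3):

```
154 8.08 0.001996007984031936 dmn_posterior
3 4.21 0.13373253493013973 None
```

— the injected posterior-DMN slow5 increase in aMCI is recovered as a
154-voxel cluster dominated by that parcel (peak t = 8.1) with
permutation cluster p ≈ 0.002, while a 3-voxel noise blob does not
survive (clusters that are not significant are left unlabelled). The companion
contrast `("HC", "aMCI")` recovers the salience-network decrease the same
way.

A YAML-configured end-to-end run (both arms, cluster tables, association
TSVs, cohort table, manifest) is available as

```bash
boldvar run-all --out out/ --seed 1 --arm both
```

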