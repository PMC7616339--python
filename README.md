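# cortexdepth

Depth-resolved cortical quantitative-MRI analysis for case–control
studies of pediatric focal epilepsy — and for any study asking *where in
the cortical depth* qT1/qT2 changes live.

Conventional morphometry often misses the widespread microstructural
alterations of drug-resistant focal epilepsy.  This package implements
the full analysis chain for probing them with quantitative relaxometry:

1. **Relaxometry** — joint nonlinear fitting (JSR) of two SPGR and three
   phase-cycled bSSFP steady-state acquisitions to voxelwise
   (M0, qT1, qT2).  SPGR follows the Ernst equation
   S = M0 sinα(1−E1)/(1−E1 cosα); bSSFP the Freeman–Hill steady state
   with the RF phase increment entering as extra per-TR precession.
2. **Laminar sampling** — equivolume depth surfaces (20/40/60/80% of
   local cortical *volume* between the WM/GM boundary and the pial
   surface, plus a level 1 mm below the boundary), with
   ribbon-constrained volume-to-surface sampling.
3. **Group inference** — vertexwise GLM Y = Xb + Zg (age, sex, and
   vertexwise thickness/curvature as nuisance), TFCE test statistics,
   Draper–Stoneman permutation, FWE correction within and across
   modalities and contrasts.  The intracortical gradient
   (80% − 20% depth) indexes depthwise organization.
4. **Lesion profiling** — per-lesion z-score depth profiles against the
   control distribution (|z| > 2 rule), transmantle probing at −1 mm,
   geodesic distance-decay curves.
5. **Classification** — 100-tree random forest on concatenated
   whole-brain qT1/qT2 gradient maps, trained on one stratum and
   evaluated on a held-out stratum, with a permutation p-value.

Because studies of this kind rarely deposit imaging data, the package
ships a first-class synthetic cohort generator (`cortexdepth.synthetic`)
producing paired white/pial hemisphere meshes, qT1/qT2 volumes with a
depth-dependent laminar profile, covariates, group effects concentrated
in superficial depths, and focal lesions with transmantle extensions.
See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a small cohort with the default planted effect (+5% qT1/qT2 at
depths ≥ 60%), extract depthwise features, and test for group
differences:

```python
import numpy as np
from cortexdepth.synthetic import CohortConfig, make_cohort, cohort_table
from cortexdepth.features import extract_depth_features, flip_hemispheres, HEMI_ORDER
from cortexdepth.inference import SurfaceGraph, depth_group_analysis
from cortexdepth.surfaces import vertex_thickness, vertex_curvature

cfg = CohortConfig(n_patients=20, n_controls=20, seed=11)
subjects = make_cohort(cfg)
table = cohort_table(subjects)

features = {"qT1": [], "qT2": []}
thick, curv = [], []
for s in subjects:
    for mod in features:
        fs = extract_depth_features(s, mod)
        features[mod].append(flip_hemispheres(fs, s.focus_side))
    thick.append(np.concatenate([vertex_thickness(s.white[h], s.pial[h]).values
                                 for h in HEMI_ORDER]))
    curv.append(np.concatenate([np.nan_to_num(vertex_curvature(s.white[h]).values)
                                for h in HEMI_ORDER]))

graph = SurfaceGraph([subjects[0].white[h] for h in HEMI_ORDER])
res = depth_group_analysis(features, table, np.vstack(thick), np.vstack(curv),
                           graph, n_perm=500, seed=7)
for key in (0.2, 0.6, 0.8, "gradient"):
    r = res[(key, "qT1", "patients>controls")]
    print(key, int((r.p_fwe_across < 0.05).sum()), "significant vertices")
```

prints (642-vertex hemispheres, 1284 vertices total):

```
0.2 0 significant vertices
0.6 1278 significant vertices
0.8 1284 significant vertices
gradient 1284 significant vertices
```

— the planted superficial effect is recovered at the 60% and 80% depths
and on the gradient map after joint FWE correction, and the untouched
20% depth stays clean.  Counts are the number of vertices with
FWE-across p < 0.05; the same run on an amplitude-0 cohort yields 0
everywhere.

A command-line interface covers the file-based stages:

```bash
cortexdepth simulate --seed 3 --out cohort/
cortexdepth fit-jsr --spgr a.nii --spgr b.nii --bssfp c.nii --bssfp d.nii --bssfp e.nii --out maps/
cortexdepth sample --white w.surf.gii --pial p.surf.gii --volume maps/qT1.nii.gz --out depths/
cortexdepth classify --cohort cohort/ --train positive --test negative --perms 999 --seed 7 --out report.json
```

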