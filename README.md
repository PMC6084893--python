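# pkpet

Quantification of dynamic [11C]PK11195 brain PET: blood-input Logan graphical
analysis (total distribution volume, V_T, with an image-derived input
function) versus reference-Logan analysis (binding potential, BP_ND, with a
supervised-cluster pseudo-reference region), together with a digital dynamic
brain phantom and test–retest reliability statistics.

## Scientific problem

[11C]PK11195 binds the 18-kDa translocator protein (TSPO), a marker of
microglial activation used to image neuroinflammation, e.g. in multiple
sclerosis. Quantifying its binding is notoriously hard:

* **Blood-input route.** The Logan plot with an arterial (or image-derived)
  input function estimates V_T, the total distribution volume. An
  image-derived input function (IDIF) from carotid-artery ROIs avoids
  arterial cannulation, but is noisy and partial-volume corrupted, and V_T
  mixes specific binding with nonspecific uptake and delivery.
* **Reference-tissue route.** Reference-Logan estimates BP_ND = DVR − 1
  without blood sampling, but PK11195 has no anatomically fixed
  reference region — TSPO can be expressed anywhere. The supervised-cluster
  approach ("SuperPK"-style) instead *finds* normal-gray-matter-like voxels
  by decomposing each voxel's time–activity curve (TAC) against kinetic
  class curves, and can **fail** when pathology is widespread.

The two estimators therefore trade bias, variance, and robustness
differently. This package implements both pipelines end to end and a
test–retest phantom experiment that measures their repeatability (TRV, aTRV,
repeatability coefficient %RC) region by region — including eroded ("shrunk")
volumes of interest and small lesions, where the methods diverge most.

Because no patient data ship with the package, a parametric dynamic phantom
is a first-class component: a 22-frame, 60-minute scan of a brain-like
geometry (cortical gray shell, white-matter interior, high-binding
thalamus-like nucleus, rim/core lesion shells, carotid tubes), rendered from
closed-form two-tissue-compartment kinetics, blurred by a 6-mm PSF, and
degraded by count-dependent noise with seeded test–retest dose jitter.

## Worked example

Simulate noiseless tissue curves from known kinetics and recover V_T and
BP_ND. Models follow the statsmodels convention: build a model, call
`fit()`, inspect the results object.

```python
from pkpet import (
    FrameSchedule, InputFunction, TissueKineticParams,
    simulate_2tcm, analytic_vt, logan_vt, reference_logan_bpnd,
)

schedule = FrameSchedule.brain_60min()          # 22 frames, 60 min
blood = InputFunction(                          # whole-blood input model
    prepeak_times=[0.0, 1.5], prepeak_values=[0.0, 40.0],
    amplitudes=[24.0, 12.0, 4.0], rates=[3.0, 0.4, 0.012],
)
target = TissueKineticParams(K1=0.12, k2=0.12, k3=0.084, k4=0.06)
reference = TissueKineticParams(K1=0.12, k2=0.12)

target_tac = simulate_2tcm(target, blood, schedule)
reference_tac = simulate_2tcm(reference, blood, schedule)

fit = logan_vt(target_tac, blood)
print(fit.summary())
print(f"analytic V_T: {analytic_vt(target):.4f}")
print()
ref_fit = reference_logan_bpnd(target_tac, reference_tac, k2_prime=reference.k2)
print(ref_fit.summary())
print(f"analytic V_T ratio - 1: {analytic_vt(target)/analytic_vt(reference) - 1:.4f}")
```

Output:

```
Logan graphical fit (blood input), t* = 30 min
  n points    : 5
  V_T         : 2.3605 (SE 0.0034)
  intercept   : -28.7166 (SE 0.1038)
  R^2         : 0.999994
analytic V_T: 2.4000

Logan graphical fit (reference input), t* = 30 min
  n points    : 5
  DVR         : 2.3570 (SE 0.0032)
  BP_ND       : 1.3570
  intercept   : -28.7198 (SE 0.0990)
  R^2         : 0.999994
analytic V_T ratio - 1: 1.4000
```

### The test–retest experiment

The full pipeline — phantom rendering, noise, IDIF extraction and blood-model
fitting, supervised-cluster reference extraction, both Logan fits on every
VOI of the erosion series and on each lesion, and the reliability summary:

```python
import pandas as pd
from pkpet import default_phantom, run_trt_experiment

result = run_trt_experiment(default_phantom(), n_subjects=10, seed=7)
rows = result.summary.query("region in ('TH', 'WM-6')")
print(rows.round(2).to_string(index=False))
frac = result.lesion_pairs.groupby("method")["trv_pct"].apply(
    lambda t: (t.abs() < 20).mean()
)
print()
print("fraction of lesions with |TRV| < 20%:")
print(frac.to_string())
```

Output (~1 minute on one CPU):

```
region    method  P  mean_trv_pct  sd_trv_pct  mean_atrv_pct  sd_atrv_pct  rc_pct
    TH    LGM_VT 10         -0.03        1.69           1.40         0.82    3.15
    TH RLGM_BPND 10         -0.11        0.41           0.32         0.27    0.80
  WM-6    LGM_VT 10          0.74        1.74           1.53         1.01    3.54
  WM-6 RLGM_BPND 10         -1.34        3.70           3.12         2.21    7.36

fraction of lesions with |TRV| < 20%:
method
LGM_VT       1.000
RLGM_BPND    0.975
```

The characteristic pattern is visible: in the high-binding thalamus-like
region BP_ND is the more repeatable measure (%RC 0.80 vs 3.15), while in the
smallest low-binding white-matter VOI (WM-6) — where BP_ND is near zero and
its TRV denominator tiny — BP_ND repeatability collapses relative to V_T (SD
of TRV 3.70 vs 1.74), and V_T keeps more small lesions under the 20 %
variability threshold.

## Command line

```sh
pkpet fit logan    --tac tissue.tsv --input blood.tsv --tstar 30 --out fit.tsv
pkpet fit reflogan --tac tissue.tsv --ref reference.tsv --k2prime 0.12
pkpet trt run      --spec phantom.yaml --subjects 10 --seed 7 --out results/
```

`trt run` writes `summary.tsv` (per-region reliability table), `lesions.tsv`
(per-lesion pairs), `pairs.tsv`, `idif_auc.tsv`, and a `manifest.json` with
all seeds. Omitting `--spec` uses the built-in default phantom; a spec YAML
can be produced with `pkpet.io.write_phantom_spec`.

## Package layout

| module | contents |
| --- | --- |
| `pkpet.frames`, `pkpet.tac` | frame schedules, time–activity curves, AUC |
| `pkpet.input_function` | piecewise-linear + tri-exponential blood model, fit |
| `pkpet.kinetics` | closed-form 2TCM simulation, analytic V_T |
| `pkpet.phantom` | parametric dynamic brain phantom, PSF, noise, test–retest pairs |
| `pkpet.voi` | region masks, erosion series, TAC/IDIF extraction |
| `pkpet.logan` | `LoganModel` / `ReferenceLoganModel` → `LoganResults` |
| `pkpet.reference` | supervised-cluster reference extraction (NNLS class decomposition) |
| `pkpet.reliability` | TRV/aTRV/%RC, AUC ratios, the experiment harness |
| `pkpet.io` | TSV/NIfTI/YAML readers and writers |
| `pkpet.cli` | the `pkpet` command |

See `docs/methods.md` for models, assumptions, parameter defaults, and
limitations.

## Reproduction

```sh
pip install --no-build-isolation -e ".[test]"
python -m pytest -q                      # full suite, ~1 minute
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities (estimator recovery
errors, noise-bias curve, erosion-direction changes, reliability statistics
of the 10-subject experiment, extraction-failure counts) from the given seed
and writes them as JSON. All simulation randomness is seeded; identical
seeds give bit-identical images and identical result tables.
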