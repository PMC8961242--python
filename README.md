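# adir — artificial double inversion recovery MRI synthesis and evaluation

Cortical grey-matter lesions in multiple sclerosis are nearly invisible on
routine clinical MRI (T1, T2, FLAIR). Double inversion recovery (DIR) —
two inversion pulses timed to null white matter and CSF so only cortical
grey matter retains signal — makes them discernible, but the sequence is
hard to set up and slow to acquire, so most scanners and most trials go
without it. `adir` implements the alternative: synthesize an *artificial*
DIR volume from the sequences every scanner already produces (3D-T1,
PD/T2), using a 3D conditional adversarial network, and quantify how well
lesion detection on the synthetic images agrees with detection on acquired
DIR.

Because clinical MRI cannot be bundled with a software package, `adir`
ships a physics-based phantom generator that stands in for the cohort:
deformed-shell brain anatomies with planted cortical lesions of known type
and location, converted to realistic T1w/PDw/T2w/DIR contrasts through
steady-state relaxation signal equations. Every downstream stage —
preprocessing, patch sampling and augmentation, adversarial training,
whole-volume prediction, lesion-level statistics — runs end-to-end on
phantoms with known ground truth.

## What is implemented

- **`adir.phantom`** — tissue phantoms (WM/GM/CSF/background + lesions),
  the DIR longitudinal-magnetization closed form
  `1 − 2e^(−TI2/T1) + 2e^(−(TI1+TI2)/T1) − e^(−TR/T1)`, a solver for the
  (TI1, TI2) pair that nulls two tissues simultaneously, and sequence
  simulation (spin echo, inversion recovery, DIR) with Gaussian noise.
- **`adir.preprocess`** — z-score over the brain mask, divide by 4, clip to
  [−1, 1]; rigid/affine resampling with cubic splines (order 0 for masks).
- **`adir.sampler`** — brain-masked patch extraction, the stochastic
  augmentation scheme (mirroring, joint rotation+scaling, per-channel
  gamma, noise, blur, channel zeroing) and the
  `floor(brain voxels / patch³)·8` epoch-size rule.
- **`adir.gan`** — U-shaped generator (instance norm, leaky ReLU, skip
  concatenation, tanh output), PatchGAN discriminator, BCE + λ·MAE losses,
  alternating Adam training (lr 2e-4, β₁ 0.5, β₂ 0.999, batch 2), and
  sliding-window prediction with overlap averaging. The conv layers are
  numpy/BLAS with hand-derived backward passes, so no deep-learning
  framework is required. `DirGan` wraps this as a scikit-learn-style
  estimator (`fit`/`predict`, `get_params`/`set_params`, fitted attributes
  `generator_`, `history_`).
- **`adir.lesion_eval`** — hyperintensity-based lesion detection with the
  3 mm² axial-area rule, greedy one-to-one centroid matching,
  precision/recall (per-subject and pooled), the two-way mixed
  absolute-agreement ICC with F test and 95% CI, and lobe/type
  contingency tables.
- **`adir.pipeline` / `adir.cli`** — the full phantom → preprocess → train
  → predict → evaluate chain, NIfTI and CSV I/O, YAML configuration with
  hashing, and the `adir` command (`phantom`, `preprocess`, `train`,
  `predict`, `evaluate`, `run`).

## Worked example

DIR physics — solve the inversion delays that null WM (T1 = 600 ms) and
CSF (T1 = 4000 ms) at TR = 6500 ms, then inspect the longitudinal
magnetization of each tissue:

```python
from adir import phantom as ph

ti1, ti2 = ph.solve_nulling_times(600, 4000, 6500)
print(f"nulling delays: TI1={ti1:.1f} ms, TI2={ti2:.1f} ms")
for name, t1 in [("WM", 600), ("GM", 950), ("CSF", 4000), ("lesion", 1100)]:
    print(f"  {name:6s} Mz/M0 = {ph.longitudinal_dir(t1, ti1, ti2, 6500):+.4f}")
```

```
nulling delays: TI1=2349.4 ms, TI2=403.8 ms
  WM     Mz/M0 = +0.0000
  GM     Mz/M0 = -0.1983
  CSF    Mz/M0 = +0.0000
  lesion Mz/M0 = -0.2245
```

WM and CSF are nulled, grey matter retains signal, and the lesion (longer
T1/T2, higher proton density) is hyperintense relative to GM — the contrast
that makes cortical lesions visible on DIR.

Lesion-level statistics — pooled precision/recall from a detection
contingency (528 lesions detected on both readings, 98 artificial-only,
168 conventional-only), and the count-agreement ICC on a simulated
15-subject cohort:

```python
import numpy as np
from adir import lesion_eval as le

m = le.MatchResult(subject_id="pooled", pairs=[], tp=528, fp=98, fn=168)
pr = le.precision_recall([m])
print(f"precision={pr.pooled_precision:.2f} recall={pr.pooled_recall:.2f}")

rng = np.random.default_rng(0)
subj = rng.poisson(40, size=15)
counts = np.stack([subj + rng.poisson(4, 15), subj + rng.poisson(4, 15)], axis=1)
res = le.icc_two_way_mixed_absolute(counts.astype(float))
print(f"ICC={res.icc:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f}, F={res.f_stat:.2f})")
```

```
precision=0.84 recall=0.76
ICC=0.945 (95% CI 0.846-0.981, F=33.73)
```

A precision of 0.84 means 84% of lesions marked on the artificial images
match a lesion location on the reference; recall 0.76 means 76% of
reference lesions were found. The ICC (two-way mixed model, absolute
agreement, single measure) quantifies how well per-subject lesion *counts*
agree between the two readings.

End-to-end on phantoms, from the shell:

```bash
adir run --seed 1 --out-dir runs/demo     # phantoms -> train -> predict -> evaluate
adir phantom --shape 64 64 64 --n-lesions 8 --seed 7 --out-dir phantom7
```

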