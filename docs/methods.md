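# Methods

This note documents the models and procedures implemented in `adir`, the
choices made where the design was genuinely open, and what the synthetic
phantom study does and does not demonstrate.

## Phantom model and signal simulation

A phantom is a deformed-shell anatomy on a regular voxel grid: background
enclosing a CSF shell, a grey-matter (GM) ribbon, and a white-matter (WM)
core. All shell boundaries are modulated by one smooth random angular
function per phantom (two low-order trigonometric terms with seeded
amplitudes in [0.02, 0.06]), so cohorts vary in shape while staying
analytically tractable. Lesions are spheres placed relative to the GM
ribbon by type: *intracortical* entirely inside the ribbon, *juxtacortical*
in WM touching the ribbon, *mixed* straddling the WM/GM boundary. When no
explicit type list is given, types are drawn with probabilities
(0.72, 0.21, 0.07) — intracortical lesions dominate in MS cohorts and mixed
lesions are rare. Lobes (frontal/temporal/parietal/occipital) come from a
fixed four-sector azimuthal parcellation; this is a stand-in for an atlas
parcellation and only needs to provide consistent labels for tabulation.

Tissue contrasts come from closed-form steady-state signal equations with
per-tissue T1/T2 (ms) and proton density PD in [0, 1]:

- spin echo: `S = PD (1 - exp(-TR/T1)) exp(-TE/T2)`
- inversion recovery: `S = PD |1 - 2 exp(-TI/T1) + exp(-TR/T1)| exp(-TE/T2)`
- double inversion recovery (first inversion at t = 0, second at t = TI1,
  excitation at t = TI1 + TI2):
  `Mz/M0 = 1 - 2 exp(-TI2/T1) + 2 exp(-(TI1+TI2)/T1) - exp(-TR/T1)`,
  and `S = PD |Mz/M0| exp(-TE/T2)`.

Default tissue values are literature-typical for 1.5 T: WM 600/80, GM
950/100, CSF 4000/2000, lesion 1100/120 ms (T1/T2) with PD 0.7, 0.85, 1.0,
0.9. The lesion's prolonged relaxation and raised PD make it hyperintense
on DIR relative to GM — the property the whole evaluation rests on.

The default protocol emulates a 1.5 T session: an MPRAGE-like T1w
(TR/TE/TI = 2700/5.03/950 ms), dual-echo TSE PD/T2 (3130/24 and 3130/85 ms),
and DIR at TR/TE = 6500/355 ms. The two DIR inversion delays are not free
parameters: a DIR protocol chooses them to null WM and CSF for the tissue
T1s at hand. `solve_nulling_times` finds that root by nested 1D bracketing
(the magnetization is strictly decreasing in TI1, giving a unique inner
root; a scan over TI2 brackets the outer root) to a residual below 1e-8;
for the default tissue table the solution is TI1/TI2 = 2349.4/403.8 ms,
which is the package default. Noise is additive Gaussian, parameterized as
a fraction of the mean GM signal; background voxels carry noise only. No
Bloch simulation, B1/B0 inhomogeneity, partial-volume mixing, Rician
magnitude bias, or k-space artifacts are modelled: downstream training needs
correct contrast *ordering*, not scanner fidelity.

## Preprocessing

Intensities are z-scored over the brain mask (not the full field of view —
air would dominate the statistics otherwise), divided by 4, and clipped to
[-1, 1]; a z-score of ±4 lands exactly on the clip boundary, so on Gaussian
data the expected clipped fraction is 2·Φ(−4) ≈ 6.3e-5. Resampling applies
an externally supplied rigid (or, when flagged, 12-dof affine) 4×4 transform
with cubic spline interpolation (order 0 for masks, which preserves discrete
label sets); the registration *search* is out of scope, and phantom
pipelines use the identity. Transforms are read as whitespace-delimited 4×4
text matrices.

## Patch sampling and augmentation

Training patches are cubes whose center voxel is drawn uniformly (with
replacement) from the brain mask; regions outside the volume are
zero-padded. The per-epoch sample count is
`floor(total brain voxels / patch_edge^3) * 8`.

Augmentation draws, per patch: mirroring per axis (p = 0.5 each); a combined
rotation+scaling (p = 0.5, per-axis angles uniform in [-90°, 90°], per-axis
scale in [0.8, 1.2], one matrix about the patch center, cubic resampling,
values re-clipped); and predictor-only intensity operations — per-channel
gamma in [0.8, 1.5] (p = 0.5, applied on intensities remapped to [0, 1]
since gamma on signed values is undefined), additive Gaussian noise with
sd 0.05 (p = 0.3), a blur with one sigma in [0.2, 1.5] shared across
channels (p = 0.3), and zeroing one random channel (p = 0.3). The three
30% operations trigger independently; mutual exclusivity would be another
defensible reading of the protocol, but independent triggers are simpler
and cover all combinations. After any effective intensity change the
predictors are re-standardized (divide by the in-patch sd, divide by 4,
clip); a gamma of exactly 1.0 changes nothing and therefore triggers no
re-standardization, keeping "gamma = 1 is the identity" exact. The target
patch receives the geometric operations only. All draws for one patch are
collected into an explicit plan object before any image work, so trigger
statistics can be audited cheaply.

## Network and training

The generator is a U-shaped fully convolutional encoder-decoder: at each of
`depth` levels one 3×3×3 convolution + instance normalization + leaky ReLU
(slope 0.2); encoder levels below the first halve the spatial extent with
stride-2 convolutions and double the filter count from `base_filters`; the
decoder mirrors this with nearest-neighbour upsampling + convolution
(avoiding checkerboard artifacts) and concatenates the same-resolution
encoder feature map before each decoder convolution; a final convolution to
one channel with tanh bounds the output to the [-1, 1] data range. The
discriminator is a PatchGAN: stride-2 kernel-4 convolution stages (instance
norm from the second stage on), then a one-strided convolution with sigmoid
producing a validity score map, each element judging one receptive field
(46 voxels for the default 3-stage stack).

Losses: the generator minimizes `BCE(D(x, G(x)), 1) + λ · MAE(G(x), y)`
with λ = `mae_weight` (default 100, the conventional weighting for
conditional adversarial translation; the adversarial-vs-reconstruction
weighting is a free parameter of the method); the discriminator minimizes
the mean of `BCE(D(x, y), 1)` and `BCE(D(x, G(x)), 0)`. Training alternates
one discriminator and one generator Adam step per batch (lr 2e-4,
β1 = 0.5, β2 = 0.999, batch size 2, 350 epochs at full scale, no
learning-rate decay). One generator forward pass serves both updates; the
discriminator treats the fake as a constant input. Training aborts on any
non-finite loss. A missing input sequence at application time is handled by
the channel-zeroing convention the augmentation teaches.

The layers are implemented directly on numpy: convolution loops over kernel
offsets, each contributing one channel-mixing GEMM against the padded
volume, with analytic backward passes (verified against
`scipy.ndimage.correlate` and finite differences). This keeps the working
set cache-resident on a single CPU, where an im2col formulation is
memory-bound.

Whole volumes are predicted by sliding-window inference: windows of
`patch_edge` at the given stride (plus end-aligned windows so the volume is
fully covered), overlapping predictions averaged with uniform weights,
output trimmed to the input grid.

## Lesion-level statistics

An automated detector stands in for the human rater: voxels exceeding
`mean + z·sd` of the GM intensity (z = 3 by default) form 26-connected
components; a component is kept if it touches the (1-voxel-dilated) GM mask
and its largest axial in-plane cross-section reaches 3 mm². Lesion type is
inferred from the GM-overlap fraction (1 → intracortical, 0 →
juxtacortical, else mixed); lobes come from an optional lobe-code map.

Two detection sets of one subject are matched greedily on ascending
centroid distance, one-to-one, accepting pairs within `tol_mm` (default
5 mm — a radius criterion is the minimal formalization of visual location
matching). Greedy matching is not cardinality-optimal on adversarial
geometry, but equals the exhaustive optimum whenever lesions are separated
by more than the tolerance, which is the operating regime. Precision is
TP/(TP+FP) and recall TP/(TP+FN) with the conventional reading as
reference; pooled values use summed counts, and subjects with a zero
denominator are excluded from the per-subject means with a logged note.

Agreement in per-subject lesion counts uses the single-measure
absolute-agreement intraclass correlation from the two-way ANOVA mean
squares,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with the F test `MSR/MSE` on (n-1, (n-1)(k-1)) degrees of freedom and 95%
confidence bounds by the F-based construction with Satterthwaite degrees of
freedom (McGraw & Wong's ICC(A,1)). A duplicated column returns exactly 1
with a degenerate interval; zero total variance is an error. The
implementation is validated against a brute-force ANOVA decomposition and
against pingouin's ICC(A,1) row.

Lobe/type tables count matched pairs (labels taken from the conventional
member), aDIR-only and cDIR-only records, with percentages of each column
total at 1 decimal; column totals equal TP/FP/FN by construction.

## Scaled-down study profile

The end-to-end learning check trains a depth-3/base-8 generator on
noiseless 32³ phantoms: 3 training and 2 held-out subjects, 4 lesions each
(radius 1.0–1.8 mm), full-volume 32³ patches, batch size 2, 6 samples per
epoch, 200 epochs (~600 optimizer steps), λ = 1000 so the adversarial term
is negligible and the check isolates the reconstruction pathway, auxiliary
discriminator slimmed to base 4 / 2 stages, augmentation off. The learning
rate for this profile is 1e-3 rather than the full-scale 2e-4: with ~600
steps instead of hundreds of thousands, the full-scale rate leaves the
model visibly under-converged (systematic shrinkage toward the mean). The
profile reaches a held-out voxelwise correlation of ~0.9–0.95 with the
analytic DIR inside the brain mask, with run-to-run spread of a few
hundredths across initialization seeds — hence the three-seed,
majority-pass design of the check.

## What the phantom study shows — and does not

Passing phantoms demonstrates that the pipeline is internally consistent:
the physics produces the DIR contrast it should, the network can learn a
voxelwise contrast mapping with small-lesion preservation, and the
statistics reproduce the reference values when fed the reference counts. The
phantoms are far easier than clinical data: piecewise-constant tissue,
perfect co-registration, no field inhomogeneity, no anatomical variability
beyond smooth shell deformation, and lesions that are geometric spheres.
Nothing here certifies clinical image quality or rater-level detectability;
the clinical headline numbers depend on human scoring of data that cannot
be regenerated computationally.

## Numerical choices

- Float32 throughout the network; Adam epsilon 1e-8; BCE probabilities
  clipped to [1e-7, 1 - 1e-7].
- He-style weight initialization scaled by 1/sqrt(fan-in), gain sqrt(2)
  (1.0 for output and score heads), per-build seeded generator.
- Nulling-time solver: 512-point scan over TI2 with Brent refinement,
  residual tolerance 1e-8.
- Spline interpolation order 3 with zero fill outside the field of view;
  order 0 wherever discrete labels must survive.
- Ties in greedy matching break on record order (stable and deterministic).
- All randomness flows through `numpy.random.default_rng` seeds; every
  pipeline stage logs its seed and a configuration hash, and identical
  configurations regenerate identical artifacts.
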