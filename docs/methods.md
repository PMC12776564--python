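# Methods

## Problem and model

Thoracic difference-EIT images are dominated by ventilation: lung tissue
swings between roughly 7 and 24 Ωm over the breathing cycle, while the
cardiac contribution to the boundary-voltage signal is an order of
magnitude weaker and concentrated in the electrically least sensitive
central region. `eitsep` reproduces, end to end in simulation, a
supervised separation approach: a convolutional network is trained on
simulated difference-EIT images to emit two maps per frame — one for the
lung-related signal and one for the heart-related signal.

The network is a *semi-Siamese U-Net*: a single convolutional encoder
(shared thoracic feature extractor) feeding two structurally identical
but independently parameterized decoders, one per organ system. Each
decoder receives the encoder's skip tensors at every resolution and ends
in a 1×1 convolution + sigmoid head. The training objective is the
multi-weighted binary cross-entropy

    E = W_lung · BCE(S(x_lung), t_lung) + W_heart · BCE(S(x_heart), t_heart)

with `S` the logistic function and BCE the pixel-mean binary
cross-entropy. Only the ratio `Wc = W_heart / W_lung` matters (the
optimizer is scale-adaptive); `W_lung` is fixed at 1 and `Wc` is swept
over {1.0, 1.5, 1.8, 2.0}. Raising `Wc` penalizes heart errors more
heavily and counteracts the lung signal's dominance in the shared
encoder's gradient. The comparison baseline is the classical
single-decoder U-Net with a 2-channel head trained under unit weights.

## Simulation pipeline

**Phantom.** A unit-disk thorax slice with background conductivity
1 S/m, two lateral lung disks (0.5 S/m) and one anterior-central heart
disk (2 S/m). Radii are drawn uniformly — lungs from [0.3, 0.6], heart
from [0.1, 0.3] (arbitrary units, domain radius 1). Lungs are nominally
at (±0.5, 0) and the heart at (0, 0.15), each jittered by ±0.1 per axis;
draws whose disks overlap or leave the domain are rejected and redrawn.
Geometric caveat: two large lungs plus a heart cannot be disjoint inside
the unit disk, so rejection necessarily truncates the accepted
lung-radius distribution near ≈0.52 even though the *draws* are uniform
to 0.6. Accepted-phantom radii are therefore not uniform over the
configured ranges, and small hearts (hardest to segment) dominate the
accepted distribution.

**Forward problem.** Linear (P1) triangular finite elements on a
structured ring mesh of the disk (default ≈1024 elements; node rings are
invariant under rotation by one electrode pitch, which gives the
rotational-symmetry oracle used in tests). Sixteen point electrodes,
adjacent-pair drive at 1 mA, and the standard adjacent measurement
scheme (13 differential pairs per drive, 208 measurements per frame).
The gauge is fixed by a zero-mean potential constraint via a Lagrange
multiplier; one sparse LU factorization per conductivity state serves
all 16 drives. Correctness anchors: the closed-form two-point-source
potential on the homogeneous disk (agreement <2 % at ≈4k elements, and
converging under refinement), exact reciprocity and conductivity-scaling
identities, and an adjoint-formula Jacobian validated against finite
differences to <1e−3 relative. Point electrodes (no contact impedance)
are used instead of the complete electrode model: difference imaging
cancels most electrode effects and no contact impedances are specified
for the simulated system.

**Reconstruction.** A GREIT-style linear matrix maps normalized voltage
differences z = (v − v_ref)/|v_ref| to a 32×32 image. The matrix is fit
on 500 simulated point targets (radius 0.05, uniform over the disk)
with desired images equal to disks of radius 0.1 at the target location,
by regularized least squares R = X Zᵀ(Z Zᵀ + λI)⁻¹. λ is set to
`noise_amplitude² · trace(ZZᵀ)/n_meas` with `noise_amplitude = 0.5`, a
spectral proxy for the community-default noise figure ≈0.5; an explicit
noise-figure bisection was tried and rejected because it over-smooths
(mean single-target localization error grows from ≈1.6 px to ≈1.8 px).
Conductivity increases map to positive pixel values; pixels whose center
leaves the unit disk are identically zero. Reconstructions of single
small targets localize to ≤2 px mean error over 50 random positions,
except in the central low-sensitivity zone where point targets blur —
a physical limitation of the adjacent-drive protocol, not of the fit.

**Dataset.** One sample = (min-max-normalized difference image of the
full phantom against the homogeneous reference; binary lung mask; binary
heart mask), masks rasterized by the pixel-center-in-disk rule on the
same 32×32 grid. Default study size: 1000 train/validation samples
(split 900/100) plus 200 independently generated test samples from a
disjoint seed stream; provenance hashes guarantee no phantom appears in
both streams. An alternative continuous-target mode (normalized
reconstructions of the lungs-only and heart-only phantoms) is available
behind `target_mode="continuous"`; metrics and defaults use the binary
mode.

## Training configuration

The paper-level recipe (Adam, weighted BCE, grid over Wc) leaves the
architecture and optimization details open; the package's defaults are:

| parameter | default | rationale |
|---|---|---|
| depth / base channels | 4 / 16 (library), 3 / 8 (study runs) | 32×32 inputs saturate quickly; the depth-3, base-8 network reaches the same test Dice as larger variants at a quarter of the single-CPU cost |
| block | conv3×3 → batch-norm → leaky ReLU (slope 0.01), twice | the heart contrast occupies only a few percent of the normalized input range; BN lets early layers amplify it, and the leak prevents decoder die-off under Adam at low heart weight |
| head bias init | −2 | starts the sigmoid outputs near the foreground prior so the large background saturates early and gradients concentrate on organ boundaries |
| optimizer | Adam, lr 3e−3, cosine-annealed to 2 %, batch 16 | fastest stable convergence found on one CPU |
| epochs | 60 (library default), 40 (study runs) | validation Dice plateaus by ≈40 epochs at the 900-sample scale |
| early stopping | patience 10 on validation loss, best weights (incl. BN statistics) restored | |
| augmentation | left-right flips | the phantom distribution is mirror-symmetric about the vertical axis, so flips are label-exact |
| loss clipping | ε = 1e−7 inside the logs | numerical floor |

Seeding: one master seed fans out (via `numpy.random.SeedSequence`) to
data generation, weight init and shuffling; identical seeds give
bit-identical datasets and training runs.

## What the simulation does and does not show

The generator emulates the *geometry and electrical contrast* of a
thorax slice and the lung-dominance problem; it does not emulate
anatomical boundary shapes, 3D current spreading, electrode movement,
contact impedance, or measurement noise. Test performance on this
synthetic family therefore bounds what the same pipeline would do on
real frames from above. Real-frame inference (`eitsep.realdata`) is
zero-shot and strictly qualitative: no co-registered ground truth
exists for the public human recording.

Under the default conditions (center jitter ±0.1, binary pixel-mask
targets, 900 training samples) the heart Dice of the semi-Siamese
network converges to ≈87–89 % with heart MAE ≈0.4 %, and the classical
U-Net baseline to ≈84–86 %. The residual heart-Dice gap to a perfect
score is a generalization floor, not an optimization failure: training
Dice keeps rising with capacity and epochs while test Dice plateaus, and
a kernel-ridge probe of the same images recovers the heart center only
to ≈0.24 px, which caps per-sample Dice of small hearts (the majority
of accepted phantoms) near the observed plateau. Configurations that
remove center jitter would make the task a three-parameter family and
drive Dice toward 1, but violate the radius-coverage property the
sampler is required to satisfy. The weight-ratio effect is visible but
modest at this problem scale: heart metrics improve from the unweighted
to the heart-weighted runs, and the dual-decoder network beats the
single-decoder baseline at every Wc; at strongly reduced problem sizes
(the fast test configuration) the Wc trend flattens into its seed noise,
which the trend checks absorb with a 1-pp tolerance.

## Numerical and degenerate-case choices

- Dice of two empty masks is 1.0 (perfect agreement on absence);
  binarization threshold 0.5 with ties counted as foreground.
- Per-sample metrics are averaged over the test set (not pooled over
  pixels); Dice uses binarized maps, MAE the continuous maps, in percent.
- Min-max image normalization maps constant images to all-zero.
- Max-pool gradient routes to the first maximum of a tied window.
- Mesh element conductivity is decided by the element centroid; the
  element-count target is met within a factor of two by ring counts.
- Overlap rejection retries 1000 draws before declaring a sampling
  config over-constrained.

## Problem sizes used by the shipped runs

The acceptance script trains three networks (Wc = 1.8, Wc = 2.0,
baseline) on the full 1000-sample study with the depth-3/base-8, 40-epoch
configuration (≈15 min on one CPU). The test suite's headline check runs
the Wc = 2.0 arm of the same configuration once; the grid-ordering check
runs the full 4-point grid + baseline over three seeds at a reduced size
(250 samples, 24 epochs, batch 8) so the whole suite stays fast. These
sizes are the package's single-CPU working points; larger runs change
the reported metrics by at most ≈1 pp (measured at 2× capacity and 2.5×
epochs).
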