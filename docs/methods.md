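# Methods

`sansml` is a virtual-experiment pipeline for small-angle neutron scattering
(SANS): it simulates 2-D detector patterns for a catalogue of analytic
form-factor models on a simplified model of the KWS-1 pinhole camera,
packages them as a labelled image dataset, and trains an ensemble of
convolutional networks that ranks candidate scattering models for a measured
pattern. This note records the model assumptions, the numerical choices and
the limits of what the tests demonstrate.

## Form-factor catalogue

The class space is a fixed 46-name catalogue; the integer class label of a
model is its 0-based rank under lexicographic ordering of the names
(`adsorbed layer` → 0 … `sphere` → 39 … `teubner strey` → 44 …
`vesicle` → 45). Thirteen representative models ship with intensity kernels —
nine isotropic (sphere, fuzzy sphere, core–shell sphere, Debye coil, DAB,
broad peak, Teubner–Strey, mass fractal, Teixeira fractal) and four
orientable (cylinder, elliptical cylinder, ellipsoid, core–shell cylinder).
The remaining names are registered without kernels so that class indices stay
stable; `register_kernel` attaches new kernels without touching the core.
Kernel formulas follow the standard SasView parameterisations with SasView
defaults as the sampling centres `p0`. Intensities are kept in arbitrary
(relative) units: classification only sees the pattern shape, so the absolute
cm⁻¹ calibration constants are dropped.

Two deliberate bound restrictions: the mass-fractal dimension is capped at
2.9 so that the analytic structure factor (which contains
sin[(D−1) arctan(qζ)]) stays inside its first, non-negative sine lobe; the
Teixeira fractal dimension is likewise capped below 3. Outside that range the
closed forms go negative and stop being physical scattering intensities.

Orientation is parameterised by the polar/azimuthal angles (θ, φ) of the
particle principal axis with the beam along +z (plus a cross-section rotation
ψ for the elliptical cylinder); the kernel evaluates the angle between the
axis and the in-plane scattering vector, a small-angle approximation in which
the longitudinal q component is neglected (q_z/q ≈ q λ/4π < 1% over the
instrument's q range).

Orientation averages use Gauss–Legendre nodes in cos θ crossed with a uniform
azimuthal grid; 76 nodes per dimension is the default, sufficient for sub-0.1%
accuracy below q ≈ 0.1 Å⁻¹ for the default geometries (the oscillatory
sinc factor of long cylinders needs ≳256 nodes at q ≈ 0.2 Å⁻¹, which the
convergence test uses).

## Polydispersity

Size parameters r are drawn from a Gaussian centred on r, truncated to
positive values by rejection (re-draw until > 0); the spread Δr may range
from 0 (monodisperse) to r/2 (very polydisperse). Orientation angles are
drawn uniformly from a window of half-width Δθ centred on the angle value;
the LHS sampler draws Δθ from [0, π], which spans perfectly oriented to fully
disordered ensembles. All distributions are sampled per neutron event, which
is what a ray-tracing virtual experiment does and what makes the Monte-Carlo
estimate an unbiased average over the polydispersity distributions.

## Virtual instrument

The beamline model keeps the components that shape a small-angle pattern and
nothing else:

- **Wavelength**: λ ∈ {4.5, 6} Å from a symmetric triangular band of 10%
  fractional FWHM (a typical velocity-selector resolution; configurable).
- **Collimation**: two square/rectangular slit apertures separated by the
  collimation length; entry and exit points are drawn uniformly in the
  apertures, fixing the incident direction. Slit settings S1 (1.0 cm),
  S2 (1.2 cm) and S3 (0.7 cm horizontal × 1.0 cm vertical) with their sample
  cells; holder thickness (1/2 mm) is carried as metadata.
- **Distances**: (collimation, sample–detector) ∈ {(8,1), (8,8), (20,20)} m.
  The full grid 2 λ × 3 distances × 3 slits × 2 holders = 36 configurations.
- **Detector**: 144 × 256 pixels at 5.25 mm pitch (≈ 0.76 × 1.34 m), beam
  centre at the grid centre, with a 4 × 4 cm beamstop. Pitch and beamstop are
  documented defaults, not published values, and are configurable.
- **Scattering**: forced-scattering importance sampling — every neutron
  scatters toward a point drawn uniformly over the detector area and carries
  the weight I(q) · cos³θ · (1 − absorption) · A_det/(N · SDD²). This is the
  standard variance-reduction device of MC instrument simulation; the
  azimuthal average of the accumulated image converges to the
  instrument-smeared 1-D intensity. The transmitted beam is omitted (the
  beamstop blocks it in the real instrument); absorption is the flat
  two-level {0, 10%} sample attribute of the sweep.
- Per-pixel sums of squared weights are accumulated alongside the counts, so
  every reduced quantity carries a Monte-Carlo standard error.

Not modelled: guide transport and the source spectrum (the wavelength band
enters directly at the selector), gravity, detector efficiency maps and
dead time, multiple scattering. Consequently simulated images are cleaner
than measured ones: no hall background, no detector artefacts — a classifier
trained here sees idealised versions of the real patterns.

The azimuthal-uniformity check is a χ² test on azimuthal sector totals inside
an annulus, with the effective event count n_eff = (Σw)²/Σw² standing in for
the Poisson count so that importance weights behave multinomially. For
isotropic models the weights within an annulus are nearly equal and the test
is exact in the limit; for oriented particles the sector totals are grossly
non-uniform and the statistic explodes. For very steep profiles (DAB,
fractals) a handful of near-beamstop pixels carries much of the weight and
the χ² approximation becomes mildly anti-conservative — the measured false
positive rate at α = 0.01 is ≈ 1.5–2% rather than 1%, i.e. isotropic images
still pass in ≥ 95% of seeded replicates.

## Sweep, cleaning, splitting, serialisation

A sweep is the Cartesian grid (model × LHS point × absorption × instrument
configuration). Parameter spaces are sampled with latin hypercubes
(`scipy.stats.qmc`): each continuous parameter is stratified over
[max(−3p0, lb), min(3p0, ub)] — the bounds rule of the original sweep, which
for positive defaults collapses to [lb, min(3p0, ub)] — with one sample per
stratum; each length parameter gets a spread dimension Δr ∈ [0, r/2] and each
angle a window half-width Δθ ∈ [0, π] as additional LHS dimensions. At the
full scale of the original campaign the grid is 46 × 100 × 2 × 36 = 331,200
records; the package reports this arithmetic without generating it.

Per-record seeds derive from `SeedSequence(base_seed, spawn_key=(label,
point, absorption_index, config_id))`, so records are reproducible
independently of execution order and the sweep is embarrassingly parallel.
Failed simulations are flagged in the metadata, never silently dropped.

Cleaning applies three rules in order: drop all-zero images; drop images
whose pixel standard deviation lies strictly below the empirical 0.02
quantile of per-image standard deviations; drop images whose maximum pixel
lies strictly above the 0.99 quantile of per-image maxima. Quantiles use the
linear-interpolation order statistic (numpy default) computed on the nonzero
set; ties at a threshold survive. On 1000 distinct values these rules remove
exactly 20 and 10 images.

Splitting is label-stratified 0.70/0.20/0.10 (train/test/validation) with
largest-share rounding per class; a class with fewer records than partitions
stays wholly in train with a warning. Partitions serialise as one HDF5 file
(root datasets `data`: n × 144 × 256 float32, `target`: n int64) plus a CSV
metadata sibling with columns `model, label, config_id, wavelength_A,
collimation_m, sdd_m, slit_id, holder_mm, absorption, seed, ok,
param:<name>…, dparam:<name>…`; write∘read is the identity.

## Preprocessing

Classifier inputs are x → log(x+1)/MaxLog (MaxLog the post-log maximum, so
outputs lie in [0,1] with max exactly 1, independent of counting statistics —
the base of the logarithm cancels in the ratio), then a bilinear resize with
half-pixel-centred coordinates from 144 × 256 to the square 180 × 180 network
input (one axis upsampled, the other downsampled). Preprocessing happens on
the fly at training/inference; stored HDF files keep raw counts as the
dataset of record.

## Classifier and ensemble

The reference architecture is a compact CNN: four conv blocks (3 × 3 kernels,
16/32/64/128 channels, each bias-free conv followed by batch normalisation,
ReLU and stride-2 max pooling) and a linear C-way head with SoftMax on the
flattened 11 × 11 × 128 feature map — under a million parameters, trainable
on one CPU core. Two design points matter here. The batch norm is what lets a
net this small train from scratch in a handful of epochs; without it the loss
creeps for tens of epochs at any stable learning rate. And the head is
deliberately position-aware rather than globally pooled: the detector radius
at which a ring or form-factor minimum sits is the discriminating feature of
a scattering pattern, and global average pooling erases exactly that
information at this network scale (measured cost on the 6-model benchmark:
about 0.12 of held-out top-1 accuracy). Large pretrained classifiers can
afford global pooling because hundreds of channels encode position
implicitly; 128 channels cannot. It runs on a small numpy layer stack
written for this package (im2col convolutions backed by BLAS matmuls, Adam,
log-sum-exp cross-entropy); GPU-scale transfer-learning architectures are out
of scope for the tested pipeline.

Training minimises batch-mean cross-entropy with Adam, batch size 64, at most
30 epochs; only full batches are drawn (the shuffled remainder differs every
epoch, so all records participate over training — and uniform batch shapes
keep the batch-norm statistics and the layer scratch buffers stable). The checkpoint rule "accept the weights of the last epoch at which
test accuracy decreased" is self-contradictory as stated in the original
protocol; the default here keeps the epoch with the best batch-average test
accuracy (the literal rule is available via `checkpoint_rule="literal"`).
Test-time accuracy is the batch-average at batch size 500 (validation 1000);
these sizes only group records for averaging — the forward pass always runs
in 64-image chunks to bound memory.

The learning rate deserves a note: 1e-5 is the documented choice for
fine-tuning large ImageNet-pretrained networks. The compact CNN trains from
scratch, where 1e-5 barely moves He-initialised weights within 30 epochs;
its default is 1e-3, and the scaled benchmark uses 2e-3 under a cosine decay
(lr · ½(1 + cos πt/T)), which is where its held-out accuracy flattens within
ten epochs. One seed governs weight initialisation and batch shuffling;
training is deterministic given the seed.

The ensemble is the arithmetic mean of member SoftMax vectors; argmax and
top-k rank ties break toward the lowest class index. Per-class
precision/recall/F1 and the confusion matrix delegate to scikit-learn behind
the package surface (classes absent from the labels are reported with
support 0 and NaN metrics); top-k accuracy and the Eq.-style cross-entropy
are implemented here. No class-imbalance correction is applied — the cleaned
sweep is mildly unbalanced and the pipeline proceeds as the full-scale campaign
does.

## The scaled-down benchmark

The full-scale campaign (46 classes, ~260k images, three pretrained
architectures, GPUs) is not desk-scale, so the package defines a scaled
stand-in whose conditions are fixed in `sansml.benchmark`: six models with
clearly distinct detector signatures (sphere, broad peak, DAB, Debye coil,
mass fractal, cylinder), 200 LHS points each, one representative instrument
configuration (6 Å, 8 m–8 m, S1, 1 mm, absorption 0), 10⁵ events per image —
1200 raw images, ≈ 1164 after cleaning, split 70/20/10. A 3-member
seed-varied compact-CNN ensemble trains for 10 epochs under the cosine
schedule. The acceptance bar is held-out Top-1 ≥ 0.80
(chance is 1/6), Top-3 ≥ 0.95, and ensemble Top-1 at least the weakest
member's. Passing it shows the whole pipeline — simulation through
recommendation — is learnable end to end at this scale; it does not certify
the full-scale accuracy figures, nor performance on measured data with real
backgrounds.

## Numerical choices and degenerate inputs

- Kernel removable singularities (sinc, 2J₁(x)/x, the sphere amplitude, the
  Debye function) switch to series below ~1e-4–1e-6 argument.
- q = 0 events in the simulator are clipped to 1e-10 Å⁻¹ before kernel
  evaluation (the beamstop removes those pixels anyway).
- Zero-spread polydispersity returns the monodisperse value exactly, not an
  MC estimate of it.
- Empty azimuthal annuli are reported as NaN with a zero pixel count, never
  as zero intensity.
- An all-zero image raises at preprocessing (MaxLog = 0) — cleaning must run
  first.
- LHS intervals that collapse to a point (p0 = 0 with lb = 0) are legal and
  produce constant samples; lb > 0 with an upper end below it is a
  configuration error.

## Limitations

- 13 of 46 catalogue entries have kernels; the rest are label placeholders
  (extensible registry).
- The instrument is a geometric abstraction of KWS-1: real pixel pitch,
  beamstop geometry and selector resolution are instrument details the
  abstraction does not pin down; the defaults are plausible and
  configurable, not asserted.
- Simulated backgrounds are the models' flat `background` parameter only; no
  instrumental background, so recommendation scores on measured data will be
  less confident than on virtual data.
- Training determinism holds for this numpy stack bit-for-bit on a given
  BLAS; across BLAS implementations accumulation order may differ in the
  last float32 ulps.
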