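# Methods

## The model

`cardiovae` implements a multi-domain β-VAE that embeds three views of one
cardiac subject in a single shared latent space:

- **ED anatomy branch** — a labeled 3D point cloud of the biventricular
  surface at end diastole (classes: LV endocardium, LV epicardium, RV
  endocardium; coordinates in mm),
- **ES anatomy branch** — the same representation at end systole, with its
  own (architecturally identical but separately parameterised) network,
- **ECG branch** — one standardized 400-sample single-beat lead II trace.

Each branch has an encoder producing a fixed-width feature; the three
features are concatenated and a single shared pair of affine heads emits the
latent mean μ and log-variance. A 12-dimensional z is drawn with the
reparameterization trick and fed to all three decoders. The anatomy encoder
is a two-stage multi-class point-set network: a shared per-point MLP over
(x, y, z, class) rows, max-pooling to a global feature, broadcast
("unpool") and concatenation with the per-point features as a skip
connection, a second shared MLP, and a final pooled feature passed through
fully connected layers. Max pooling makes the encoding exactly invariant to
point order. The anatomy decoder first maps z through an MLP to a coarse
multi-class cloud (750 points/class at full scale) and then folds a tiled
2-D grid around every coarse point, conditioned on (grid coordinates,
coarse point, z, class one-hot), to emit the dense cloud (12,000
points/class). The ECG branch uses two convolution–ELU–batch-norm blocks
with stride 2, average pooling and two dense layers; its decoder mirrors
this with a dense block and two transposed convolutions whose padding is
solved by the config validator so the output length equals the input length
exactly (lengths must be divisible by stride², e.g. 400 or 100).

### Loss

`L_total = L_ED + L_ES + γ·L_ECG + β·L_KL`, with each anatomy term a sum
over the three classes of `CD(coarse) + α·CD(dense)` (classes unweighted),
`L_ECG` the mean squared error on standardized traces, and `L_KL` the
analytic diagonal-Gaussian KL against N(0, I). The Chamfer distance is the
symmetric mean nearest-neighbour distance; the training variant uses squared
Euclidean point distances for smoother gradients, while every *reported*
Chamfer value is unsquared and in mm. Training anatomy terms are expressed
in physical units (mm², via the stored normalization scale) even though the
networks operate on centred, rescaled coordinates — the weighting schedule
below is calibrated against mm-scale reconstruction magnitudes, and keeping
the loss in normalized units would make the fixed β ceiling ~3,600× more
aggressive than intended (we observed exactly this failure mode: at
normalized scale the KL term flattens the posterior and reconstruction
degrades by a factor ~2).

### Annealing schedule

α (dense anatomy weight) and γ (ECG weight) start at 0.01 and 0.1 and ramp
linearly to 1 over the first 40% of training; β starts at 0.01 and ramps
from 50% to 90% of training, capping at 0.25. The ordering constraint — β
rises only after α and γ have finished — is validated at construction. At
full scale training runs 150,000 Adam steps with batch 4; the scaled-down
preset used throughout the tests runs 2,000 steps.

### Optimisation stack

No deep-learning framework is assumed: the package contains a compact
reverse-mode autodiff engine over NumPy arrays (`cardiovae.nn`) with exactly
the ops the model needs (dense algebra, max pooling, gathers for Chamfer,
1-D un/fold for convolutions) plus Adam. Every op's gradient is verified
against central differences in the test suite. Heavy math is BLAS-bound, so
CPU training of the scaled-down model takes ~2 minutes.

## Synthetic cohort generator

The generator emulates a paired cardiac-MRI + ECG cohort. Each subject has
ground-truth factors: global size, long-axis elongation, basal tilt, wall
thickness, endocardial ED→ES contraction scale c (LV EF = 1 − c³), and ECG
wave parameters (R/P/T amplitudes, QRS width). Both domains are driven by
the same factors, with explicit couplings (size→R amplitude, contraction→T
amplitude) — the cross-domain structure the VAE must learn.

Geometry is analytic: the LV endocardium is a basally truncated prolate
ellipsoid (short semi-axis 30 mm, axis ratio 1.8, basal cut at 0.25·b), the
epicardium the same surface offset outward by the wall thickness (7.5 mm
default), and the RV endocardium a laterally clipped larger ellipsoid cap.
All three shells are convex by construction (ellipsoid ∩ half-spaces), so
convex-hull volumes are exact meshing oracles; an alpha-shape mesher is
available for concave clouds. At ES the endocardial axes scale by c
(default 0.75 → EF 58%), the epicardium by (1+c)/2 (a crude
wall-incompressibility approximation that keeps LV mass roughly constant
across phases), and the RV by 1.02·c (EF ≈ 55%). Default dimensions were
calibrated once so a healthy population reproduces textbook biventricular
means — LV EDV ≈ 140 ml, ESV ≈ 59 ml, mass ≈ 102 g, RV EDV ≈ 168 ml — with
realistic SDs arising from the factor distributions.

Surfaces are sampled on a quasi-uniform Fibonacci lattice in the surface
parameterisation with small Gaussian jitter (0.4 mm). This mirrors real
surface reconstructions, whose mesh vertices are near-regular rather than
Poisson-scattered; it also makes "mean nearest-neighbour spacing" a
meaningful sampling-resolution statistic (≈ √(area/n) rather than half of
it). The ECG is a sum of five Gaussian deflections (P, Q, R, S, T at fixed
beat fractions 0.15/0.38/0.42/0.46/0.72) plus additive noise, standardized
per trace.

The optional disease phenotype is a dilated, poorly contracting heart with
coupled ECG changes: size +0.18, contraction +0.07 (lower EF), wall −1 mm,
T amplitude −0.35, QRS width +0.25. A logistic regression on the *true*
factors separates it almost perfectly (AUROC ≈ 1.0), which upper-bounds
what any latent-code classifier can achieve.

What the generator does **not** emulate: real anatomical shape detail
(trabeculation, valve planes, septal curvature), acquisition artefacts
(slice misalignment, segmentation error), multi-beat ECG variability,
torso-dependent lead projection, and atria. Passing tests therefore show
that the architecture, losses and analyses behave correctly on data with
genuine cross-domain structure — not that the model is validated on real
cardiac cohorts.

## Evaluation metrics

- **Chamfer distance** (unsquared, mm) per class and phase for anatomy
  reconstruction; verified against a brute-force double loop to 1e-9.
- **RMSE and PRD** for ECG reconstruction, computed after per-signal
  min-max normalization of both traces (PRD normalises by the energy of its
  first argument, the prediction). Per-signal rather than per-dataset
  min-max was chosen because it is the only variant that is well defined
  for a single trace; raw-scale variants remain available.
- **MMD** with a Gaussian kernel for population comparison; bandwidth from
  the median pairwise-distance heuristic over the pooled sample unless
  given. The default estimator is the unbiased U-statistic (clamped at zero
  before the square root); a biased V-statistic option exists because
  ratios against a same-distribution baseline need a strictly positive
  denominator.
- **Clinical metrics** from meshed point clouds: cavity volumes (ml), LV
  mass (wall volume × 1.05 g/ml), SV = EDV − ESV, EF = SV/EDV·100.
  Population summaries report mean ± sample SD (n−1), with EF averaged as a
  mean of per-subject ratios.
- **Combined representation** for cross-domain population tests: the nine
  clinical metrics z-scored against a reference population and rescaled so
  the clinical block's total variance equals the ECG block's, concatenated
  with the ECG samples.

## Latent-space applications

The sampling prior for generation is empirical — per-dimension mean and SD
of the posterior means μ over the training set (the aggregate posterior
never matches N(0, I) exactly at finite β; sampling from it yields more
realistic cohorts). SD over μ's is the default statistic; the mean predicted
σ is available as an alternative. Traversal decodes z vectors varying one
component by ±k prior SDs with the rest at the prior mean. Disease
classification uses the latent μ of a held-out 150/150 cohort as features
for an L2-regularised logistic regression (C = 1, features standardized
inside each fold) under stratified 10-fold cross-validation; single-domain
baselines are separately trained VAEs restricted to the anatomy or ECG
branches, not masked passes through the joint model.

## Numerical and design choices

- Class labels enter the encoder as a numeric fourth coordinate (0/1/2,
  scale configurable); one-hot encoding is available behind a config
  switch.
- Input clouds are centred per record (ED and ES jointly, preserving their
  relative offset) and scaled by a fixed 60 mm constant; the inverse
  transform restores decoder outputs to mm, so reported Chamfer values are
  physical.
- Evaluation-mode reconstruction decodes z = μ (no sampling); training
  draws one z per record per step.
- The unsquared Chamfer adds 1e-12 inside the square root to keep the
  gradient finite at coincident points.
- Split sizes use the largest-remainder method (deterministic, sums
  exactly); z-scoring uses the population SD (÷N).
- Degenerate inputs raise rather than warn: constant traces for either
  normalization, < 4 points or coplanar geometry for meshing, non-positive
  wall volume for mass, single-class labels for classification, zero
  encoder spread for prior fitting.
- Adam defaults to lr 1e-4 at full scale; the scaled-down recipe uses 1e-3
  (constant; an optional cosine decay is available but off by default).

## Scaled-down study conditions

CPU-scale experiments (tests and the acceptance script) use 300 synthetic
subjects (190/10/100 train/validation/test), 256 input points per class,
16 coarse / 64 dense output points per class, 100-sample ECGs, latent size
12, 2,000 training steps at batch 4, with the annealing milestones at the
same fractions as the full-scale schedule. At these conditions the model
reaches held-out Chamfer ≈ 4.6 mm (below the ≈ 6.1 mm sampling resolution
of the input clouds), a latent dimension correlating |r| > 0.8 with the
true size factor, virtual ECG populations within 3× the two-half MMD of
real data, monotone LV-EDV latent traversals, and disease classification
AUROC > 0.99 for the multi-domain code. Statistical assertions are
evaluated as majority votes over three training seeds (classification over
five).

## Known limitations

- The analytic shells cannot express concave local anatomy; Chamfer floors
  are set by sampling density rather than anatomical detail.
- Convex-hull volumes are only exact for convex shapes; for concave clouds
  the alpha-shape option depends on a sensible alpha radius.
- The autodiff engine is single-threaded NumPy; full-scale (36,000-point,
  150,000-step) training is architecturally supported and shape-checked but
  not practical on CPU.
- BatchNorm running statistics make encoder outputs depend on training
  history; eval-mode determinism is guaranteed, cross-machine bit equality
  is not.
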