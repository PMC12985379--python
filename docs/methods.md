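# Methods

This note documents the models, algorithms and numerical choices in
`ciondose`: what the synthetic beamlet generator emulates, how the
transformer dose engine is built and trained, how the evaluation metrics
are defined, and where the genuinely open design choices were settled.

## Problem setting

A scanned carbon-ion treatment is delivered as thousands of pencil beams
(beamlets). Planning needs, per beamlet and per voxel, the absorbed dose
`d` (Gy), and the linear-quadratic coefficients `alpha` (1/Gy) and `beta`
(1/Gy^2) that feed the RBE-weighted dose

    D_RBE = (sqrt(alpha_x^2 + 4 beta_x (alpha d + beta d^2)) - alpha_x) / (2 beta_x),

where `alpha_x`, `beta_x` are the reference photon parameters. Monte Carlo
transport produces all three at gold-standard accuracy but is too slow for
adaptive workflows; `ciondose` implements the alternative: transformer
models that map a beams-eye-view CT subvolume plus the beam energy to the
three volumes in a single forward pass, trained on per-beamlet ground
truth.

## Synthetic ground truth

Real patient CTs and Monte Carlo ground truth are not distributable, so
the package ships a first-class simulator whose outputs have the
statistical and geometric structure of the real training data. It is an
analytic surrogate, not a transport code; its contracts are shape
properties, not dosimetric realism.

- **Phantoms.** Water background (HU 0) on a 1 mm isotropic grid,
  48x48 lateral voxels and 260-360 mm depth at full scale; complexity
  classes add 1-3 transverse bone slabs (HU 700-1200, 3-15 mm thick)
  and/or 1-2 embedded air ellipsoids (HU -1000). Proximal all-air slices
  (every voxel < -900 HU) are removed before use.
- **Stopping power.** Piecewise-linear HU -> relative stopping power with
  knots (-1000 -> 0.001, 0 -> 1.0, 1000 -> 1.55, 3000 -> 2.3) — the
  standard clinical calibration shape. Water-equivalent depth (WED) is the
  cumulative RSP sum along the central beam axis; the beam nozzle (a thin
  PMMA slab plus air gap upstream of the phantom) is folded into a
  constant 4.6 mm water-equivalent offset instead of being transported.
- **Range-energy relation.** `R(E) = a E^p` fitted through R(115) = 30 mm
  and R(260) = 130 mm of water (`p ~= 1.80`), covering the therapeutic
  energy window 115-260 MeV/u used throughout.
- **Depth dose.** Three components per beamlet, parameterized in WED:
  a primary-carbon term (rising plateau, sigmoid range falloff, Gaussian
  Bragg peak of width sigma combining range straggling ~1.2% of R and the
  momentum-spread contribution `2p (dp/p) R`, floored at 0.8 mm; hard
  zero 5 mm beyond the range with a cosine taper), and two fragment
  groups that build up with depth and decay exponentially beyond the
  range (25 mm and 12 mm tails). Amplitudes give a peak-to-entrance ratio
  of ~4.5 and a fragment tail below 15% of the peak. A global scale of
  25 Gy*mm^2 per 1e7 primaries puts voxel doses in the clinical range
  (peaks of roughly 0.6-2.6 Gy per 1e7 primaries).
- **Lateral spread.** Gaussian with sigma(z) = sqrt(sigma0^2 + (0.02 z)^2),
  sigma0 from an energy-dependent entrance FWHM (8 mm at 115 MeV/u to
  5 mm at 260 MeV/u, linear). Fragment groups are spread 2.0x and 1.5x
  wider than the primary, so the mixed-field quantities vary laterally as
  well as in depth.
- **alpha/beta.** Per-species alpha and beta are monotone piecewise-linear
  tables in residual range (primary alpha 0.30 -> 1.50 /Gy from entrance
  to peak; fragments lower), mimicking the local-effect-model behaviour of
  rising effectiveness toward the Bragg peak. Voxel values are dose-
  averaged over species: `alpha = sum(a_i D_i) / sum(D_i)`, and by default
  the TRiP98 convention for beta, `sqrt(beta) = sum(sqrt(b_i) D_i) /
  sum(D_i)`; direct beta dose-averaging is available as a switch. Voxels
  with zero dose are undefined and returned as NaN for the caller to mask
  (the generator stores 0 there).
- **Energy sampling.** A 30-step discrete ladder spans 115-260 MeV/u. An
  energy is eligible if its usage count is at most 99% of the ladder
  maximum (least-used energies always stay eligible, so equal counts bind
  nothing) and its Bragg peak lies inside the phantom; ineligible draws
  are resampled. Small datasets can exhaust the cap for short phantoms;
  the pipeline then relaxes the cap rather than aborting.

What the generator does **not** emulate: nuclear fragmentation physics,
multiple-scattering tails, CT noise and artifacts, couch-angle geometry,
or anatomical texture. Passing tests therefore demonstrate that the
learning and evaluation machinery works end to end on data with the right
structure — not clinical accuracy on patients.

## Preprocessing

Volumes are cropped to the model grid — symmetric 24x24 mm laterally
around the beam axis, first 240 mm of depth anchored at the proximal face
(shorter beamlets are padded distally with air/zeros). Inputs are
normalized to [0, 1]: CT by the fixed window [-1000, 3000] HU, energy
linearly from [115, 260] MeV/u, and (for the alpha/beta models) the
predicted dose by its own maximum. Labels are *not* normalized; they are
scaled once — dose x1, alpha x10, beta x1e3 — so all three targets have
ranges of order 1-30 and the loss thresholds are interpretable. Training
masks zero labels below 1% of the thresholding-dose maximum: the "MC
mask" thresholds on the ground-truth dose (used for dose-model training),
the "AI mask" on the dose-model prediction (used for alpha/beta training
and at inference, so train and test conditions match).

## Models

All three models share the backbone: each depth slice of the input volume
is encoded into one token by a small convolutional encoder (two stride-2
3x3 convolutions and a linear projection), a learned embedding of the
normalized energy is prepended as token 0, learned positional embeddings
are added, and a pre-norm transformer with **causal** self-attention runs
over the sequence. Causality matches the physics — the field at depth z
is determined by the material upstream — and supplies the cumulative-WED
computation the dose mapping needs. A per-token decoder (two-layer MLP
whose output layer produces the whole 2D slice) maps depth tokens back to
slices; a softplus keeps outputs positive.

The alpha/beta models run two parallel encoder-transformer streams — one
over the CT, one over the thresholded, max-normalized predicted dose,
each with its own energy token — and merge them with a cross-attention
block in which the CT stream provides the queries and the dose stream the
keys/values, followed by the decoder. At inference the chain is strict:
the alpha/beta models only ever see the dose model's output (zeroed below
1% of its maximum), never the ground truth.

Design notes:

- The decoder is a dense per-token MLP rather than an upsampling
  convolution stack: the output layer already mixes the full lateral
  plane, and it keeps the decoder's memory traffic proportional to the
  output size, which dominates CPU runtime at these grid sizes.
- Dropout sits on the token embeddings and after every attention and MLP
  sublayer, in every configuration, because Monte-Carlo-dropout inference
  reuses the same layers.
- Cross-attention direction (CT queries, dose keys/values) and energy
  conditioning as a prepended token are configurable choices; FiLM-style
  conditioning was considered and not adopted.
- Presets: full scale (24,24,240 grid, embed 64, 4 layers) and a test
  preset (16,16,96 grid, embed 32, 2 layers for the dose model and 1 per
  alpha/beta stream, ~30k parameters) sized so the complete study runs on
  one CPU in minutes. The alpha/beta models already have two streams plus
  a cross block, so one layer per stream keeps their capacity comparable
  to the dose model at roughly half the runtime.

The networks run on a small in-repo reverse-mode autodiff engine over
numpy (float32 working precision; the finite-difference gradient checks
in the test suite run in float64 and are the correctness contract).
Training uses Adam.

## Losses and training schedule

The composite training loss is

    L = MSE + w_mask * MaskedMSE + w_depth * DepthLoss + w_region * RegionMaskedMSE

- `MaskedMSE`: mean squared error over only the voxels whose squared
  error exceeds eps^2 (0.001 in each target's scaled label units;
  configurable) — concentrates gradient on the Bragg-peak region.
- `DepthLoss`: mean squared difference of forward depth differences
  (voxel paired with its next-depth neighbour) — penalizes wrong axial
  gradients, invariant to constant offsets.
- `RegionMaskedMSE`: mean squared error over voxels whose *ground truth*
  exceeds 60% of the sample maximum — the peak region itself. The region
  is never defined by the prediction.

Selection masks are piecewise constant in the prediction, so they are
treated as constants of the iterate during backpropagation. In batches,
per-sample thresholds ("sample maximum") are used and per-sample means
are averaged.

The schedule is staged: two blocks of MSE-only epochs, then two blocks
with the composite loss; the learning rate is reset at each block
boundary and cosine-decayed within a block (restarts help escape the
blurred local minimum MSE converges to). Full scale uses 4 x 28 epochs;
the test preset 4 x 8, preserving the proportions. Weights lie on the
lattice {0, 0.2, ..., 1.0}; `grid_search_weights` trains one scaled-down
model per candidate and keeps the best validation gamma pass rate (ties:
smaller L1, then lexicographic). The shipped defaults (dose: w_depth 0.2,
w_region 0.2; alpha/beta: additionally w_mask 0.2) came from small-scale
search on the synthetic data; the full 216-candidate lattice is exposed
but not run by default.

## Evaluation

- **Gamma analysis.** Global criterion: gamma^2 = (dD / (p_d * max(ref)))^2
  + (|r| / dta)^2 minimized over displacements |r| <= 3*dta; voxels with
  reference dose below 10% of the reference maximum are excluded, and the
  default scope is the AI mask applied to both volumes. Two modes:
  `interpolated` (trilinear sampling on a step of dta/4, displacements
  visited in increasing |r| with early termination once no voxel can
  improve) and `voxel` (voxel-center displacements only — exactly
  reproducible by a brute-force oracle, and the mode used in the pipeline
  summaries). Undefined results (empty evaluated set) are `None`, never 0
  or 100. The test suite pins the voxel mode to an independent
  nested-loop oracle (exact agreement away from gamma == 1 ties) and the
  interpolated mode to an independent dense-sampling oracle (<= 0.5
  percentage points).
- **Isodose Dice.** Regions above 1%, 30% and 70% of each volume's own
  maximum; Dice = 2|A n B| / (|A| + |B|), with the GT voxel count
  reported alongside.
- **IDD metrics.** The integrated depth dose is the lateral slice sum
  (float64). R80 is the distal-most linearly-interpolated crossing of 80%
  of the profile maximum, scanned from the distal end — multi-peaked
  profiles can therefore jump between peaks, which is the known failure
  mode of automatic range detection. Delta-Dmax and RMSE are normalized
  by the reference profile maximum. The MC mask is applied to the ground
  truth and the AI mask to the prediction before profiling.
- **Mask discrepancy.** Voxels in the MC mask but not the AI mask
  ("lost", reported as a fraction of MC-mask voxels, with the mean/std of
  the ground-truth dose over them) and vice versa ("gained").
- **MCD uncertainty.** 30 stochastic forward passes of the complete chain
  with dropout rate 0.2; per-voxel mean/std volumes and the gamma pass
  rate of every individual run (mean and std over runs reported).

## Problem sizes

The test preset runs the whole study at reduced size: 250 + 25 phantoms
(500 training/validation + 50 test beamlets) on the 16x16x96 grid with
4 x 8 epochs, evaluated at 3%/3 mm; the acceptance script uses 200 + 20
phantoms of the same preset. These sizes keep a complete simulate-train-
evaluate cycle in the ten-minute range on a single CPU while leaving the
full-scale configuration (48x48 phantoms, 24x24x240 grid, 4 x 28 epochs,
1%/1 mm) available unchanged.

## Numerical choices and edge cases

- Training in float32 (memory-bandwidth-bound on CPU); gradient checks
  and metric accumulations in float64. BLAS reductions are not bit-
  deterministic across runs, so "identical" forward passes are asserted
  to ~1 ulp of float32, not bit-exact.
- Masked losses return 0 on an empty selection; mixing returns NaN at
  zero total dose; thresholding an all-zero dose, an all-air phantom, or
  a Bragg peak beyond the phantom raise typed errors
  (`DegenerateInputError`, `BraggPeakOutsideError`).
- Label scaling factors are serialization constants written into
  `meta.json`, preventing silent double scaling.
- NIfTI-1 (float32, 1 mm isotropic, quantity tag in the header
  `descrip`) is the interchange format; spacing mismatches are rejected
  at read time.
- Every dataset and summary embeds the hash of the configuration that
  produced it.

## Known limitations

- The surrogate physics has no transport: lateral heterogeneity is only
  felt through the central-axis WED, fragment buildup is schematic, and
  absolute dose levels are calibrated only to the right order of
  magnitude.
- The full-scale preset is defined but training it on CPU is slow; all
  shipped results use the test preset.
- The grid search ships with a reduced default lattice; exhausting all
  216 candidates is left to the user.
- Alpha/beta accuracy is bounded by dose-model quality (the chain
  propagates its errors), which mirrors the intended deployment but means
  a weak dose checkpoint degrades everything downstream.
- Monte-Carlo-dropout uncertainty of the desk-scale models is spread
  along the whole high-dose channel rather than concentrated at the
  Bragg peak: the std-map maximum typically sits at the distal falloff
  (where the ground truth is already below a few percent of its maximum)
  or in the entrance channel. Sharp peak-localized uncertainty appears
  only for much better-converged models than the small presets train.
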