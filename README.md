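# ciondose

A per-pencil-beam dose engine for carbon-ion radiotherapy research:
transformer models that predict, from a beams-eye-view CT subvolume and
the beam energy, the absorbed dose `d` and the linear-quadratic
coefficients `alpha` and `beta` needed for RBE-weighted dose calculation —
plus everything around them: a synthetic beamlet simulator that generates
training data with the structure of Monte-Carlo-scored pencil beams, the
staged custom-loss training schedule, and the physics evaluation suite
(3D gamma analysis, isodose Dice, depth-dose range metrics,
Monte-Carlo-dropout uncertainty).

## Who this is for

Medical-physics and ML researchers who want a self-contained, CPU-runnable
testbed for learning-based particle dose calculation: every component — data
generation, preprocessing, model, loss, metric — is importable, tested, and
small enough to read.

## The model in brief

A carbon pencil beam deposits dose with a sharp Bragg peak at the end of
its range; its biological effectiveness also peaks there, captured by the
linear-quadratic parameters. In a mixed field of the primary ion and its
fragments, voxel coefficients are dose-averaged over species `i`:

    alpha = sum_i alpha_i D_i / sum_i D_i
    sqrt(beta) = sum_i sqrt(beta_i) D_i / sum_i D_i    (TRiP98 convention)

and the RBE-weighted dose follows from

    D_RBE = (sqrt(alpha_x^2 + 4 beta_x (alpha d + beta d^2)) - alpha_x) / (2 beta_x).

The dose model encodes each 2D depth slice of the normalized CT into a
token, prepends an energy token, and runs a causal transformer over depth
(the field at depth z depends only on material upstream). The alpha/beta
models add a second stream over the thresholded predicted dose and merge
the two streams by cross-attention; at inference they only ever see the
dose model's own output. Training is staged — two blocks of MSE epochs,
then two blocks of the composite loss

    L = MSE + w_mask * MaskedMSE + w_depth * DepthLoss + w_region * RegionMaskedMSE

with a learning-rate reset per block. See `docs/methods.md` for the full
account.

## Worked example

```bash
python examples/simulate_beamlet.py
```

prints, for a 180 MeV/u beamlet on a phantom with bone slabs and an air
cavity:

```
phantom shape (mm):        (48, 48, 355)
beam energy:               180.0 MeV/u, FWHM 6.66 mm
R80 range in phantom:      63.0 mm
peak dose (central axis):  1.253 Gy / 1e7 primaries
peak-to-entrance (IDD):    4.57
alpha range:               0.198 - 1.474 1/Gy
beta range:                0.0100 - 0.0295 1/Gy^2
```

The R80 (depth where the laterally-integrated dose falls to 80% of its
maximum) lands well short of the ~80 mm water range of 180 MeV/u because
the bone slabs shorten the range; `alpha` tops out near the Bragg peak,
which is what makes carbon biologically advantageous — and what the
models must learn. Other examples: `gamma_analysis.py` (gamma pass rate
and Dice of a shifted dose), `train_small_model.py` (a two-minute
training run), `rbe_weighted_dose.py`, `mcd_uncertainty.py`.

There is also a thin CLI: `ciondose simulate`, `ciondose pipeline`,
`ciondose evaluate` (see `--help`).

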