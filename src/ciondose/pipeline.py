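"""End-to-end workflow: simulate -> preprocess -> train -> predict -> evaluate.

The full-scale configuration mirrors the study conditions (48x48 lateral
phantoms cropped to a 24x24x240 model grid, 30-energy ladder, 4 x 28-epoch
schedule); the test preset runs the identical workflow at reduced size
(16x16x96 grid, 4 x 8 epochs) so it completes on one CPU in minutes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import beamlets, evaluation, io, phantoms, preprocess
from .grids import CTVolume, FieldVolume
from .losses import LossThresholds, LossWeights
from .model import (ABModel, DoseModel, ModelConfig, PredictionChain,
                    mcd_forward, predict_chain, threshold_dose_input)
from .preprocess import normalize_ct, normalize_energy
from .training import TrainingArrays, TrainSchedule, train

log = logging.getLogger(__name__)

COMPLEXITY_MIX = ("homogeneous", "layered", "cavity", "mixed")


@dataclass
class RunConfig:
    """Fully materialized pipeline configuration (no hidden defaults)."""

    preset: str = "full"
    # simulator
    n_phantoms: int = 250
    n_test_phantoms: int = 25
    phantom_lateral: int = 48
    phantom_depth_range: tuple[int, int] = (260, 360)
    complexity_mix: tuple[str, ...] = COMPLEXITY_MIX
    ladder_size: int = 30
    beams_per_phantom: int = 2
    # preprocessing
    model_grid: tuple[int, int, int] = (24, 24, 240)
    train_val_split: float = 0.95
    # model
    embed_dim: int = 64
    n_layers: int = 4
    ab_n_layers: int | None = None  # transformer depth per alpha/beta stream
    n_heads: int = 4
    channels: int = 8
    dropout_rate: float = 0.2
    train_dropout_rate: float = 0.05
    # training
    epochs_per_block: int = 28
    base_lr: float = 2e-3
    batch_size: int = 10
    loss_weights: dict = field(default_factory=lambda: {
        "dose": {"w_mask": 0.0, "w_depth": 0.2, "w_region": 0.2},
        "alpha": {"w_mask": 0.2, "w_depth": 0.2, "w_region": 0.2},
        "beta": {"w_mask": 0.2, "w_depth": 0.2, "w_region": 0.2},
    })
    eps_sq: float = 0.001
    theta_frac: float = 0.6
    # evaluation
    gamma_dose_criterion: float = 0.01
    gamma_distance_mm: float = 1.0
    gamma_low_threshold: float = 0.10
    mcd_runs: int = 30
    mcd_rate: float = 0.2
    seed: int = 0
    format_version: int = io.FORMAT_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return io.config_hash(self.to_dict())

    def model_config(self, target: str) -> ModelConfig:
        layers = self.n_layers
        if target != "dose" and self.ab_n_layers is not None:
            layers = self.ab_n_layers
        return ModelConfig(
            target=target, grid_shape=tuple(self.model_grid),
            embed_dim=self.embed_dim, n_layers=layers,
            n_heads=self.n_heads, channels=self.channels,
            dropout_rate=self.dropout_rate,
            seed=self.seed + {"dose": 1, "alpha": 2, "beta": 3}[target],
        )

    def schedule(self, target: str) -> TrainSchedule:
        e = self.epochs_per_block
        return TrainSchedule(
            phases=[(e, "mse"), (e, "mse"), (e, "custom"), (e, "custom")],
            base_lr=self.base_lr, batch_size=self.batch_size,
            seed=self.seed + 100 + {"dose": 1, "alpha": 2, "beta": 3}[target],
        )

    def weights_for(self, target: str) -> LossWeights:
        return LossWeights(**self.loss_weights[target])

    def thresholds(self) -> LossThresholds:
        return LossThresholds(eps_sq=self.eps_sq, theta_frac=self.theta_frac)

    def gamma_params(self, distance=None, dose=None) -> evaluation.GammaParams:
        dta = self.gamma_distance_mm if distance is None else distance
        dd = self.gamma_dose_criterion if dose is None else dose
        return evaluation.GammaParams(
            dose_criterion=dd, distance_criterion=dta,
            low_dose_threshold=self.gamma_low_threshold,
            search_radius=3.0 * dta, interp_step=min(0.25 * dta, 1.0))


def test_config(seed: int = 0, **overrides) -> RunConfig:
    """The scaled-down study conditions: 16x16x96 grid, 4 x 8 epochs."""
    cfg = RunConfig(
        preset="test", n_phantoms=250, n_test_phantoms=25,
        phantom_lateral=16, phantom_depth_range=(100, 140),
        model_grid=(16, 16, 96), embed_dim=32, n_layers=2, ab_n_layers=1,
        channels=6,
        epochs_per_block=8, seed=seed,
        gamma_dose_criterion=0.03, gamma_distance_mm=3.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class BeamletRecord:
    """One simulated beamlet kept on the (uncropped) phantom grid."""

    name: str
    ct: CTVolume
    dose: FieldVolume
    alpha: FieldVolume
    beta: FieldVolume
    energy: float
    complexity: str
    phantom_seed: int
    split: str


def simulate_dataset(cfg: RunConfig, seed: int | None = None,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[BeamletRecord], io.DatasetManifest]:
    """Generate phantoms and per-beamlet ground truth.

    Each phantom receives ``beams_per_phantom`` pencil beams with distinct
    ladder energies (energies are resampled on collision and when the Bragg
    peak would fall outside the phantom). The train/val split is at the
    phantom level. Deterministic given (cfg, seed).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ladder = beamlets.EnergyLadder(
        energies=np.linspace(115.0, 260.0, cfg.ladder_size))
    records: list[BeamletRecord] = []
    entries = []
    n_total = cfg.n_phantoms + cfg.n_test_phantoms
    n_train = int(round(cfg.n_phantoms * cfg.train_val_split))
    if cfg.n_phantoms >= 2:  # keep at least one validation phantom
        n_train = min(n_train, cfg.n_phantoms - 1)

    for pi in range(n_total):
        if pi < n_train:
            split = "train"
        elif pi < cfg.n_phantoms:
            split = "val"
        else:
            split = "test"
        complexity = cfg.complexity_mix[pi % len(cfg.complexity_mix)]
        ph_seed = int(rng.integers(0, 2**31 - 1))
        ct = phantoms.generate_phantom(
            ph_seed, complexity,
            shape=(cfg.phantom_lateral, cfg.phantom_lateral),
            depth_range=cfg.phantom_depth_range)
        ct = phantoms.remove_proximal_air_slices(ct)
        chosen: list[float] = []
        for bi in range(cfg.beams_per_phantom):
            for _ in range(20):  # distinct-energy resampling
                e = beamlets.sample_energy(ladder, ct, seed=rng, relax_cap=True)
                if e not in chosen:
                    break
            chosen.append(e)
            spec = beamlets.BeamletSpec(energy=e, seed=ph_seed + bi)
            dose, alpha, beta = beamlets.generate_ground_truth(ct, spec)
            name = f"ph{pi:04d}_b{bi}"
            rec = BeamletRecord(name=name, ct=ct, dose=dose, alpha=alpha,
                                beta=beta, energy=e, complexity=complexity,
                                phantom_seed=ph_seed, split=split)
            records.append(rec)
            entries.append({"name": name, "energy": e, "complexity": complexity,
                            "seed": ph_seed, "fwhm0": spec.fwhm, "split": split})
            if out_dir is not None:
                io.write_beamlet_dir(
                    Path(out_dir) / name, ct, dose, alpha, beta,
                    {"name": name, "energy": e, "complexity": complexity,
                     "seed": ph_seed, "fwhm0": spec.fwhm, "split": split,
                     "ladder_counts": ladder.counts.tolist(),
                     "config_hash": cfg.hash})
    manifest = io.DatasetManifest(entries=entries, config_hash=cfg.hash)
    if out_dir is not None:
        manifest.save(Path(out_dir) / "manifest.json")
    return records, manifest


# ---------------------------------------------------------------------------
# Preprocessing into training arrays
# ---------------------------------------------------------------------------


def _cropped_arrays(rec: BeamletRecord, cfg: RunConfig):
    grid = tuple(cfg.model_grid)
    ct = preprocess.crop_to_model_grid(rec.ct, grid=grid)
    dose = preprocess.crop_to_model_grid(rec.dose, grid=grid)
    alpha = preprocess.crop_to_model_grid(rec.alpha, grid=grid)
    beta = preprocess.crop_to_model_grid(rec.beta, grid=grid)
    return ct, dose, alpha, beta


def build_dose_arrays(records: list[BeamletRecord], cfg: RunConfig
                      ) -> TrainingArrays:
    """Dose-model training arrays: MC-masked ground-truth dose labels."""
    cts, ens, labels = [], [], []
    for rec in records:
        ct, dose, _, _ = _cropped_arrays(rec, cfg)
        mask = preprocess.threshold_mask(dose, source="MC").mask
        cts.append(normalize_ct(ct).astype(np.float32))
        ens.append(normalize_energy(rec.energy))
        labels.append((dose.values * mask).astype(np.float32))
    return TrainingArrays(ct=np.stack(cts), energy=np.asarray(ens),
                          label=np.stack(labels))


def build_ab_arrays(records: list[BeamletRecord], cfg: RunConfig,
                    target: str, dose_pred: np.ndarray) -> TrainingArrays:
    """Alpha/beta training arrays.

    Labels are AI-masked (1% of the *predicted* dose maximum) and scaled;
    the dose input is the thresholded prediction, exactly as at inference.
    """
    cts, ens, labels, dins = [], [], [], []
    for i, rec in enumerate(records):
        ct, _, alpha, beta = _cropped_arrays(rec, cfg)
        fieldv = alpha if target == "alpha" else beta
        din = threshold_dose_input(dose_pred[i])
        if din.max() > 0:
            mask = din > 0
        else:  # degenerate prediction: fall back to an empty mask
            mask = np.zeros_like(din, dtype=bool)
        label = preprocess.scale_labels(fieldv) * mask
        cts.append(normalize_ct(ct).astype(np.float32))
        ens.append(normalize_energy(rec.energy))
        labels.append(label.astype(np.float32))
        dins.append(din.astype(np.float32))
    return TrainingArrays(ct=np.stack(cts), energy=np.asarray(ens),
                          label=np.stack(labels), dose_input=np.stack(dins))


def predict_dose_batch(model: DoseModel, arrays: TrainingArrays,
                       batch: int = 10) -> np.ndarray:
    from .autodiff import Tensor, no_grad

    outs = []
    with no_grad():
        for lo in range(0, len(arrays), batch):
            sl = slice(lo, lo + batch)
            outs.append(model(Tensor(arrays.ct[sl]),
                              Tensor(arrays.energy[sl])).data)
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _region_metric(model, arrays: TrainingArrays, theta_frac: float) -> float:
    """Mean per-sample region-masked error of a model on a validation set."""
    from .losses import region_masked_mse

    pred = (predict_dose_batch(model, arrays) if isinstance(model, DoseModel)
            else _predict_ab_batch(model, arrays))
    vals = [region_masked_mse(arrays.label[i].astype(float), pred[i],
                              theta_frac=theta_frac)
            for i in range(len(arrays)) if arrays.label[i].max() > 0]
    return float(np.mean(vals))


def _predict_ab_batch(model: ABModel, arrays: TrainingArrays,
                      batch: int = 10) -> np.ndarray:
    from .autodiff import Tensor, no_grad

    outs = []
    with no_grad():
        for lo in range(0, len(arrays), batch):
            sl = slice(lo, lo + batch)
            outs.append(model(Tensor(arrays.ct[sl]), Tensor(arrays.energy[sl]),
                              Tensor(arrays.dose_input[sl])).data)
    return np.concatenate(outs)


def _checkpoint_region_metrics(model, hist: dict, val_arrays: TrainingArrays,
                               theta_frac: float) -> dict[str, float]:
    """Region-masked validation error at the MSE-only vs final checkpoint.

    Checkpoint index 1 is the end of the second MSE block (the "MSE-only"
    model); the final state is the end of the custom-loss blocks.
    """
    final_state = model.state_dict()
    metric_custom = _region_metric(model, val_arrays, theta_frac)
    model.load_state_dict(hist["checkpoints"][1])
    metric_mse = _region_metric(model, val_arrays, theta_frac)
    model.load_state_dict(final_state)
    return {"mse_only": metric_mse, "custom": metric_custom}


def run_pipeline(cfg: RunConfig, seed: int | None = None,
                 out_dir: str | Path | None = None,
                 return_artifacts: bool = False):
    """Run the complete workflow; returns a JSON-serializable summary.

    Stages: simulate -> preprocess -> train dose -> train alpha/beta on the
    thresholded dose predictions -> predict the chain on the test split ->
    evaluate (gamma, Dice, IDD, mask discrepancy) -> Monte-Carlo-dropout
    uncertainty on a test beamlet. With ``return_artifacts`` the trained
    chain and the simulated records are returned alongside the summary.
    """
    seed = cfg.seed if seed is None else seed
    cfg = replace(cfg, seed=seed)
    log.info("simulating dataset (%d + %d phantoms)",
             cfg.n_phantoms, cfg.n_test_phantoms)
    records, manifest = simulate_dataset(cfg, seed)
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "val"]
    test_recs = [r for r in records if r.split == "test"]

    dose_train = build_dose_arrays(train_recs, cfg)
    dose_val = build_dose_arrays(val_recs, cfg)
    dose_test = build_dose_arrays(test_recs, cfg)

    log.info("training dose model")
    dose_model = DoseModel(cfg.model_config("dose"))
    dose_hist = train(dose_model, dose_train, cfg.schedule("dose"),
                      weights=cfg.weights_for("dose"),
                      thresholds=cfg.thresholds(), val_data=dose_val,
                      dropout_rate=cfg.train_dropout_rate)
    region_metrics = {"dose": _checkpoint_region_metrics(
        dose_model, dose_hist, dose_val, cfg.theta_frac)}

    log.info("predicting doses for alpha/beta training inputs")
    pred_train = predict_dose_batch(dose_model, dose_train)
    pred_val = predict_dose_batch(dose_model, dose_val)

    ab_models: dict[str, ABModel] = {}
    ab_hist = {}
    for target in ("alpha", "beta"):
        log.info("training %s model", target)
        arrays = build_ab_arrays(train_recs, cfg, target, pred_train)
        val_arrays = build_ab_arrays(val_recs, cfg, target, pred_val)
        m = ABModel(cfg.model_config(target))
        ab_hist[target] = train(m, arrays, cfg.schedule(target),
                                weights=cfg.weights_for(target),
                                thresholds=cfg.thresholds(),
                                val_data=val_arrays,
                                dropout_rate=cfg.train_dropout_rate)
        ab_models[target] = m
        region_metrics[target] = _checkpoint_region_metrics(
            m, ab_hist[target], val_arrays, cfg.theta_frac)

    chain = PredictionChain(dose_model=dose_model,
                            alpha_model=ab_models["alpha"],
                            beta_model=ab_models["beta"])

    log.info("evaluating %d test beamlets", len(test_recs))
    params = cfg.gamma_params()
    reports = []
    for i, rec in enumerate(test_recs):
        _, gdose, galpha, gbeta = _cropped_arrays(rec, cfg)
        d, a, b = predict_chain(chain, dose_test.ct[i], dose_test.energy[i])
        rep = evaluation.evaluate_beamlet(
            gt={"dose": gdose.values, "alpha": galpha.values,
                "beta": gbeta.values},
            pred={"dose": d, "alpha": a, "beta": b},
            params=params, mode="voxel")
        reports.append(rep)

    summary: dict = {"config_hash": cfg.hash, "seed": seed,
                     "n_test_beamlets": len(test_recs)}
    for q in ("dose", "alpha", "beta"):
        vals = [r.gpr_percent.get(q) for r in reports]
        summary[f"gpr_{q}"] = evaluation.summarize_gpr(vals)
    for lv in evaluation.DICE_LEVELS:
        vals = [r.dice[lv] for r in reports if r.dice[lv] is not None]
        summary[f"dice_{int(lv * 100)}"] = {
            "median": float(np.median(vals)), "min": float(np.min(vals))}
    summary["delta_r80_mm_median"] = float(np.median(
        [r.delta_r80_mm for r in reports]))
    summary["delta_dmax_percent_median"] = float(np.median(
        [r.delta_dmax_percent for r in reports]))
    summary["rmse_idd_percent_median"] = float(np.median(
        [r.rmse_idd_percent for r in reports]))
    summary["lost_voxel_fraction_mean"] = float(np.mean(
        [r.lost_voxel_fraction for r in reports]))
    summary["train_history"] = {
        "dose_final_train_loss": dose_hist["train_loss"][-1],
        "alpha_final_train_loss": ab_hist["alpha"]["train_loss"][-1],
        "beta_final_train_loss": ab_hist["beta"]["train_loss"][-1],
    }
    summary["region_metric_validation"] = region_metrics

    log.info("Monte-Carlo-dropout uncertainty")
    # prefer a homogeneous (water) test phantom for the uncertainty fixture
    mcd_idx = next((i for i, r in enumerate(test_recs)
                    if r.complexity == "homogeneous"), 0)
    _, gdose, galpha, gbeta = _cropped_arrays(test_recs[mcd_idx], cfg)
    runs = mcd_forward(chain, dose_test.ct[mcd_idx],
                       float(dose_test.energy[mcd_idx]),
                       n_runs=cfg.mcd_runs, rate=cfg.mcd_rate, seed=seed + 7)
    mcd = evaluation.mcd_summary(
        runs, ref={"dose": gdose.values, "alpha": galpha.values,
                   "beta": gbeta.values},
        params=params, mode="voxel")
    summary["mcd"] = {q: {"gpr_mean": mcd.gpr_mean[q],
                          "gpr_std": mcd.gpr_std[q],
                          "n_runs": len(mcd.gpr_runs[q])}
                      for q in mcd.gpr_runs}

    if out_dir is not None:
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.save(out / "manifest.json")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        io.save_config(cfg.to_dict(), out / "config.yaml")
        rows = []
        for rec, rep in zip(test_recs, reports):
            rows.append({
                "name": rec.name, "energy": rec.energy,
                "complexity": rec.complexity,
                "gpr_dose": rep.gpr_percent.get("dose"),
                "gpr_alpha": rep.gpr_percent.get("alpha"),
                "gpr_beta": rep.gpr_percent.get("beta"),
                "dice_1": rep.dice[0.01], "dice_30": rep.dice[0.30],
                "dice_70": rep.dice[0.70],
                "delta_r80_mm": rep.delta_r80_mm,
                "delta_dmax_percent": rep.delta_dmax_percent,
                "rmse_idd_percent": rep.rmse_idd_percent,
                "lost_voxel_fraction": rep.lost_voxel_fraction,
            })
        pd.DataFrame(rows).to_csv(out / "per_beamlet.csv", index=False)
    if return_artifacts:
        artifacts = {
            "chain": chain, "records": records, "reports": reports,
            "dose_test": dose_test, "test_records": test_recs,
            "mcd_summary": mcd, "mcd_index": mcd_idx, "config": cfg,
            "histories": {"dose": dose_hist, **ab_hist},
        }
        return summary, artifacts
    return summary


__all__ = ["RunConfig", "test_config", "simulate_dataset", "BeamletRecord",
           "build_dose_arrays", "build_ab_arrays", "predict_dose_batch",
           "run_pipeline"]
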