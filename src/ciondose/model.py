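"""Transformer models for per-beamlet dose and alpha/beta prediction.

The dose model encodes each depth slice of the normalized beams-eye-view CT
into a token, prepends a learned embedding of the normalized beam energy,
runs a causal transformer over the token sequence and decodes each depth
token back into a 2D slice. Causal attention matches the physics: the field
at depth z is determined by the material upstream of z.

The alpha/beta models add a second encoder-transformer stream over the
(thresholded, max-normalized) predicted dose and merge the two streams with
a cross-attention block in which the CT stream provides the queries and the
dose stream the keys/values, followed by the slice decoder.

Outputs pass through softplus, so they are positive everywhere; the labels
being regressed are the scaled training labels (dose in Gy per 1e7
primaries, alpha x 10, beta x 1e3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff
from .autodiff import Tensor, concat, no_grad
from .grids import DegenerateInputError
from .nn import (Adam, LayerNorm, Linear, Module, SliceDecoder, SliceEncoder,
                 TransformerBlock, dropout)
from .preprocess import MASK_THRESHOLD_FRACTION, unscale_labels

TARGETS = ("dose", "alpha", "beta")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults follow the full-scale preset."""

    target: str = "dose"
    grid_shape: tuple[int, int, int] = (24, 24, 240)
    embed_dim: int = 64
    n_layers: int = 4
    n_heads: int = 4
    mlp_ratio: int = 2
    channels: int = 8
    dropout_rate: float = 0.2
    causal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        gx, gy, gz = self.grid_shape
        if gx % 4 or gy % 4:
            raise ValueError("lateral grid must be divisible by 4")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


def test_preset(target: str = "dose", **overrides) -> ModelConfig:
    """Small CPU-friendly configuration on a reduced (16,16,96) grid."""
    cfg = ModelConfig(target=target, grid_shape=(16, 16, 96), embed_dim=32,
                      n_layers=2, n_heads=4, channels=6)
    return replace(cfg, **overrides) if overrides else cfg


class _Stream(Module):
    """Slice encoder + energy token + positional embedding + transformer."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        gx, gy, gz = cfg.grid_shape
        self.cfg = cfg
        self.encoder = SliceEncoder((gx, gy), 1, cfg.channels, cfg.embed_dim, rng)
        self.energy_proj = Linear(1, cfg.embed_dim, rng)
        self.pos = Tensor(0.02 * rng.standard_normal((gz + 1, cfg.embed_dim)),
                          requires_grad=True)
        self.blocks = [
            TransformerBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_ratio, rng,
                             causal=cfg.causal)
            for _ in range(cfg.n_layers)
        ]

    def __call__(self, vol: Tensor, energy: Tensor, rate: float,
                 rng: np.random.Generator | None) -> Tensor:
        B = vol.shape[0]
        gx, gy, gz = self.cfg.grid_shape
        slices = vol.transpose(0, 3, 1, 2).reshape(B * gz, gx, gy, 1)
        tokens = self.encoder(slices).reshape(B, gz, self.cfg.embed_dim)
        e_tok = self.energy_proj(energy.reshape(B, 1, 1))
        x = concat([e_tok, tokens], axis=1) + self.pos
        x = dropout(x, rate, rng)
        for blk in self.blocks:
            x = blk(x, rate=rate, rng=rng)
        return x  # (B, gz + 1, E); token 0 is the energy token


class DoseModel(Module):
    """CT + energy -> absorbed dose grid."""

    def __init__(self, cfg: ModelConfig):
        if cfg.target != "dose":
            raise ValueError("DoseModel requires cfg.target == 'dose'")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.stream = _Stream(cfg, rng)
        self.ln_out = LayerNorm(cfg.embed_dim)
        gx, gy, _ = cfg.grid_shape
        self.decoder = SliceDecoder((gx, gy), cfg.channels, cfg.embed_dim, rng)

    def __call__(self, ct_norm: Tensor, energy_norm: Tensor,
                 rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        B = ct_norm.shape[0]
        gx, gy, gz = self.cfg.grid_shape
        x = self.stream(ct_norm, energy_norm, rate, rng)
        depth_tokens = self.ln_out(x[:, 1:, :])
        out = self.decoder(depth_tokens.reshape(B * gz, self.cfg.embed_dim))
        out = out.reshape(B, gz, gx, gy).transpose(0, 2, 3, 1)
        return out.softplus()


class ABModel(Module):
    """CT + energy + predicted dose -> alpha (or beta) grid."""

    def __init__(self, cfg: ModelConfig):
        if cfg.target not in ("alpha", "beta"):
            raise ValueError("ABModel requires cfg.target in {'alpha','beta'}")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.ct_stream = _Stream(cfg, rng)
        self.dose_stream = _Stream(cfg, rng)
        self.cross = TransformerBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_ratio,
                                      rng, causal=False, cross=True)
        self.ln_out = LayerNorm(cfg.embed_dim)
        gx, gy, _ = cfg.grid_shape
        self.decoder = SliceDecoder((gx, gy), cfg.channels, cfg.embed_dim, rng)

    def __call__(self, ct_norm: Tensor, energy_norm: Tensor, dose_in: Tensor,
                 rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        B = ct_norm.shape[0]
        gx, gy, gz = self.cfg.grid_shape
        # normalize the dose input to [0, 1] per sample (inputs only are
        # normalized; labels stay in scaled physical units)
        dmax = dose_in.data.reshape(B, -1).max(axis=1).reshape(B, 1, 1, 1)
        dose_n = dose_in * Tensor(1.0 / np.where(dmax > 0, dmax, 1.0))
        ct_tok = self.ct_stream(ct_norm, energy_norm, rate, rng)
        dose_tok = self.dose_stream(dose_n, energy_norm, rate, rng)
        merged = self.cross(ct_tok, rate=rate, rng=rng, context=dose_tok)
        depth_tokens = self.ln_out(merged[:, 1:, :])
        out = self.decoder(depth_tokens.reshape(B * gz, self.cfg.embed_dim))
        out = out.reshape(B, gz, gx, gy).transpose(0, 2, 3, 1)
        return out.softplus()


def build_dose_model(cfg: ModelConfig) -> DoseModel:
    return DoseModel(cfg)


def build_ab_model(cfg: ModelConfig) -> ABModel:
    return ABModel(cfg)


def threshold_dose_input(dose: np.ndarray) -> np.ndarray:
    """Zero predicted dose below 1% of its own maximum (the AI mask rule)."""
    dose = np.asarray(dose)
    if dose.ndim == 3:
        m = dose.max()
        return np.where(dose > MASK_THRESHOLD_FRACTION * m, dose, 0.0)
    flat_max = dose.reshape(dose.shape[0], -1).max(axis=1)
    thr = (MASK_THRESHOLD_FRACTION * flat_max).reshape(-1, 1, 1, 1)
    return np.where(dose > thr, dose, 0.0)


@dataclass
class PredictionChain:
    """Dose model feeding thresholded dose into the alpha and beta models."""

    dose_model: DoseModel
    alpha_model: ABModel
    beta_model: ABModel
    mask_threshold: float = MASK_THRESHOLD_FRACTION


def predict_chain(
    chain: PredictionChain,
    ct_norm: np.ndarray,
    energy_norm: float | np.ndarray,
    rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full chain on one sample or a batch.

    Returns (dose, alpha, beta) in physical units (labels unscaled by 1/10
    and 1/1e3). The alpha/beta models always consume the dose model's
    thresholded output, never a ground-truth dose. Raises
    :class:`DegenerateInputError` when the predicted dose is all zero.
    """
    single = np.asarray(ct_norm).ndim == 3
    ct = np.asarray(ct_norm, dtype=float)
    if single:
        ct = ct[None]
    en = np.atleast_1d(np.asarray(energy_norm, dtype=float))
    with no_grad():
        dose = chain.dose_model(Tensor(ct), Tensor(en), rate=rate, rng=rng).data
        if dose.max() <= 0:
            raise DegenerateInputError("predicted dose is identically zero")
        dose_in = threshold_dose_input(dose)
        alpha_s = chain.alpha_model(Tensor(ct), Tensor(en), Tensor(dose_in),
                                    rate=rate, rng=rng).data
        beta_s = chain.beta_model(Tensor(ct), Tensor(en), Tensor(dose_in),
                                  rate=rate, rng=rng).data
    alpha = unscale_labels(alpha_s, "alpha")
    beta = unscale_labels(beta_s, "beta")
    if single:
        return dose[0], alpha[0], beta[0]
    return dose, alpha, beta


def mcd_forward(
    chain: PredictionChain,
    ct_norm: np.ndarray,
    energy_norm: float,
    n_runs: int = 30,
    rate: float = 0.2,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Monte Carlo dropout over the complete prediction chain.

    Runs ``n_runs`` forward passes with dropout active in all three models;
    each run's stochastic dose output is propagated into the alpha/beta
    models. Seeded and reproducible.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        runs.append(predict_chain(chain, ct_norm, energy_norm,
                                  rate=rate, rng=rng))
    return runs


__all__ = [
    "ModelConfig", "test_preset", "DoseModel", "ABModel", "PredictionChain",
    "build_dose_model", "build_ab_model", "predict_chain", "mcd_forward",
    "threshold_dose_input", "Adam", "autodiff",
]
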