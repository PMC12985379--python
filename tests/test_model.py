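"""Model contracts: shapes, positivity, determinism, chaining, MC dropout."""

from dataclasses import replace

import numpy as np
import pytest

from ciondose.autodiff import Tensor
from ciondose.grids import DegenerateInputError
from ciondose.model import (ABModel, DoseModel, ModelConfig, PredictionChain,
                            build_ab_model, build_dose_model, mcd_forward,
                            predict_chain, threshold_dose_input)
from ciondose.model import test_preset as small_preset
from ciondose.nn import Adam

TINY = ModelConfig(target="dose", grid_shape=(8, 8, 12), embed_dim=16,
                   n_layers=1, n_heads=2, channels=4)


def tiny_cfg(target):
    return replace(TINY, target=target)


@pytest.fixture(scope="module")
def tiny_chain():
    return PredictionChain(
        dose_model=build_dose_model(tiny_cfg("dose")),
        alpha_model=build_ab_model(tiny_cfg("alpha")),
        beta_model=build_ab_model(tiny_cfg("beta")))


def tiny_input(seed=0, B=2):
    r = np.random.default_rng(seed)
    return (r.uniform(0, 1, (B, 8, 8, 12)).astype(np.float32),
            r.uniform(0, 1, B).astype(np.float32))


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(target="let")
        with pytest.raises(ValueError):
            ModelConfig(grid_shape=(10, 10, 12))  # not divisible by 4
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=30, n_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)

    def test_wrong_target_for_builder(self):
        with pytest.raises(ValueError):
            build_dose_model(tiny_cfg("alpha"))
        with pytest.raises(ValueError):
            build_ab_model(tiny_cfg("dose"))

    def test_parameter_count_reported(self):
        m = build_dose_model(tiny_cfg("dose"))
        assert m.n_parameters > 1000


class TestDoseModel:
    def test_output_shape_and_positivity(self):
        m = build_dose_model(tiny_cfg("dose"))
        ct, en = tiny_input()
        out = m(Tensor(ct), Tensor(en))
        assert out.shape == ct.shape
        assert np.all(out.data >= 0)

    def test_eval_mode_deterministic(self):
        m = build_dose_model(tiny_cfg("dose"))
        ct, en = tiny_input()
        a = m(Tensor(ct), Tensor(en)).data
        b = m(Tensor(ct), Tensor(en)).data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_energy_conditioning_is_live(self):
        m = build_dose_model(tiny_cfg("dose"))
        ct, en = tiny_input()
        a = m(Tensor(ct), Tensor(en)).data
        b = m(Tensor(ct), Tensor(en * 0.3 + 0.1)).data
        assert not np.allclose(a, b)

    def test_full_preset_shapes(self):
        cfg = small_preset("dose")
        m = build_dose_model(cfg)
        r = np.random.default_rng(0)
        ct = r.uniform(0, 1, (1,) + cfg.grid_shape).astype(np.float32)
        out = m(Tensor(ct), Tensor(np.array([0.5], dtype=np.float32)))
        assert out.shape == ct.shape

    def test_single_step_decreases_mse(self):
        """Gradient flow: one Adam step lowers the sample's MSE."""
        m = build_dose_model(tiny_cfg("dose"))
        ct, en = tiny_input(seed=5, B=1)
        y = Tensor(np.abs(np.random.default_rng(6).normal(1, 0.3, ct.shape)))
        opt = Adam(m.parameters(), lr=1e-3)
        pred = m(Tensor(ct), Tensor(en))
        loss0 = ((pred - y) * (pred - y)).mean()
        opt.zero_grad()
        loss0.backward()
        opt.step()
        pred1 = m(Tensor(ct), Tensor(en))
        loss1 = ((pred1 - y) * (pred1 - y)).mean()
        assert float(loss1.data) < float(loss0.data)


class TestABModel:
    def test_dose_stream_is_live(self):
        m = build_ab_model(tiny_cfg("alpha"))
        ct, en = tiny_input()
        dose = np.abs(np.random.default_rng(1).normal(1, 0.3, ct.shape))
        a = m(Tensor(ct), Tensor(en), Tensor(dose)).data
        b = m(Tensor(ct), Tensor(en), Tensor(np.zeros_like(dose))).data
        assert not np.allclose(a, b)

    def test_shape_and_positivity(self):
        m = build_ab_model(tiny_cfg("beta"))
        ct, en = tiny_input()
        out = m(Tensor(ct), Tensor(en), Tensor(ct))
        assert out.shape == ct.shape and np.all(out.data >= 0)

    def test_dropout_passes_differ_rate_zero_identical(self):
        m = build_ab_model(tiny_cfg("alpha"))
        ct, en = tiny_input()
        rng = np.random.default_rng(0)
        a = m(Tensor(ct), Tensor(en), Tensor(ct), rate=0.3, rng=rng).data
        b = m(Tensor(ct), Tensor(en), Tensor(ct), rate=0.3, rng=rng).data
        assert not np.allclose(a, b)
        c = m(Tensor(ct), Tensor(en), Tensor(ct), rate=0.0, rng=rng).data
        d = m(Tensor(ct), Tensor(en), Tensor(ct), rate=0.0, rng=rng).data
        np.testing.assert_allclose(c, d, atol=1e-6)


class TestThresholdDoseInput:
    def test_one_percent_zeroing(self):
        dose = np.array([[[1.0, 0.005, 0.02]]])
        out = threshold_dose_input(dose)
        np.testing.assert_allclose(out[0, 0], [1.0, 0.0, 0.02])

    def test_batched(self):
        dose = np.stack([np.array([[[1.0, 0.005]]]), np.array([[[0.1, 0.0009]]])])
        out = threshold_dose_input(dose)
        assert out[0, 0, 0, 1] == 0.0 and out[1, 0, 0, 1] == 0.0
        assert out[1, 0, 0, 0] == 0.1


class TestPredictChain:
    def test_output_units_and_shapes(self, tiny_chain):
        ct, en = tiny_input(B=1)
        d, a, b = predict_chain(tiny_chain, ct[0], float(en[0]))
        assert d.shape == a.shape == b.shape == (8, 8, 12)
        assert np.all(d >= 0) and np.all(a >= 0) and np.all(b >= 0)
        # alpha/beta come back in physical units (labels unscaled)
        raw_alpha = tiny_chain.alpha_model(
            Tensor(ct), Tensor(en[:1]),
            Tensor(threshold_dose_input(d)[None]))
        assert a.max() == pytest.approx(raw_alpha.data[0].max() / 10.0, rel=1e-5)

    def test_chain_uses_predicted_dose(self, tiny_chain):
        """alpha/beta react when the dose entering the chain changes."""
        ct, en = tiny_input(B=1)
        _, a1, _ = predict_chain(tiny_chain, ct[0], float(en[0]))
        a2 = tiny_chain.alpha_model(
            Tensor(ct), Tensor(en[:1]),
            Tensor(np.zeros((1, 8, 8, 12), dtype=np.float32))).data[0] / 10.0
        assert not np.allclose(a1, a2)

    def test_deterministic(self, tiny_chain):
        ct, en = tiny_input(B=1)
        r1 = predict_chain(tiny_chain, ct[0], float(en[0]))
        r2 = predict_chain(tiny_chain, ct[0], float(en[0]))
        for x, y in zip(r1, r2):
            np.testing.assert_allclose(x, y, atol=1e-6)


class TestMcdForward:
    def test_zero_rate_zero_variance(self, tiny_chain):
        ct, en = tiny_input(B=1)
        runs = mcd_forward(tiny_chain, ct[0], float(en[0]), n_runs=3, rate=0.0,
                           seed=1)
        doses = np.stack([r[0] for r in runs])
        # zero up to BLAS reduction jitter (~1 ulp of float32)
        np.testing.assert_allclose(doses.std(axis=0), 0.0, atol=1e-6)

    def test_thirty_runs_with_dropout(self, tiny_chain):
        ct, en = tiny_input(B=1)
        runs = mcd_forward(tiny_chain, ct[0], float(en[0]), n_runs=30,
                           rate=0.2, seed=2)
        assert len(runs) == 30
        doses = np.stack([r[0] for r in runs])
        assert doses.std(axis=0).max() > 0

    def test_seeding_reproducible(self, tiny_chain):
        ct, en = tiny_input(B=1)
        r1 = mcd_forward(tiny_chain, ct[0], float(en[0]), n_runs=3, rate=0.2,
                         seed=9)
        r2 = mcd_forward(tiny_chain, ct[0], float(en[0]), n_runs=3, rate=0.2,
                         seed=9)
        for (a1, _, _), (a2, _, _) in zip(r1, r2):
            np.testing.assert_allclose(a1, a2, atol=1e-6)

    def test_invalid_args_rejected(self, tiny_chain):
        ct, en = tiny_input(B=1)
        with pytest.raises(ValueError):
            mcd_forward(tiny_chain, ct[0], float(en[0]), n_runs=1)
        with pytest.raises(ValueError):
            mcd_forward(tiny_chain, ct[0], float(en[0]), rate=1.0)
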