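"""Regression-network components: RevIN, TCN, ASB, GIFM, multi-scale CNN."""

import numpy as np
import pytest

from apyield import nn
from apyield.apyieldnet import (ASB, GIFM, APYieldNet, APYieldNetConfig,
                                DataScaler, MultiScaleCNN, RevInState, TCN,
                                apyieldnet_forward, asb_transform, gifm_fuse,
                                multiscale_cnn, revin_denormalize,
                                revin_normalize, tcn_encode)
from apyield.autodiff import Tensor, dft_matrices


class TestRevIN:
    def test_round_trip_inverse(self, rng):
        x = rng.standard_normal((7, 18)) * 50 + 100
        xn, state = revin_normalize(x)
        back = revin_denormalize(xn, state)
        assert np.max(np.abs(back - x) / (np.abs(x) + 1e-9)) < 1e-5

    def test_hand_computed_standardization(self):
        x = np.arange(1.0, 8.0).reshape(7, 1)  # [1..7]
        xn, state = revin_normalize(x)
        assert xn.mean() == pytest.approx(0.0, abs=1e-12)
        assert xn.std() == pytest.approx(1.0, abs=1e-12)
        assert state.mean[0] == pytest.approx(4.0)

    def test_constant_channel_floors_std(self):
        x = np.full((7, 2), 3.3)
        xn, state = revin_normalize(x)
        np.testing.assert_allclose(xn, 0.0, atol=1e-9)  # affine bias follows
        assert np.all(state.std >= nn.EPS)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            revin_normalize(np.ones((1, 18)))


class TestTCN:
    def test_zero_input_zero_init_biases_gives_zero(self, rng):
        tcn = TCN(3, 8, 3, (1, 2), nn.seeded_rng(0))
        out = tcn_encode(np.zeros((7, 3)), tcn)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_causality_future_perturbation(self, rng):
        tcn = TCN(5, 8, 3, (1, 2), nn.seeded_rng(1))
        x = rng.standard_normal((7, 5))
        y0 = tcn_encode(x, tcn)
        x2 = x.copy()
        x2[6] += 10.0  # perturb only the last month
        y1 = tcn_encode(x2, tcn)
        np.testing.assert_array_equal(y0[:6], y1[:6])

    def test_kernel_one_identity_weights_is_linear_map(self):
        conv = nn.Conv1d(3, 3, 1, nn.seeded_rng(0), causal=True)
        conv.weight.data[0] = np.eye(3)
        conv.bias.data[:] = 0.0
        x = np.array([[1., 2., 3.], [4., 5., 6.], [7., 8., 9.]])
        out = conv(Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, x)


class TestASB:
    def test_identity_configuration(self, rng):
        asb = ASB(7, 6).identity_config()
        x = rng.standard_normal((7, 6))
        out = asb_transform(x, asb)
        assert np.max(np.abs(out - x)) < 1e-6

    def test_weight_doubling_doubles_harmonic(self):
        """Doubling the learnable weight on a sine's conjugate bin pair
        doubles that harmonic's amplitude (DFT oracle)."""
        T = 8
        t = np.arange(T)
        x = np.sin(2 * np.pi * 2 * t / T).reshape(T, 1)  # pure bin-2 sine
        asb = ASB(T, 1).identity_config()
        asb.w_re.data[2, 0] = 2.0
        asb.w_re.data[T - 2, 0] = 2.0
        out = asb_transform(x, asb)
        np.testing.assert_allclose(out, 2 * x, atol=1e-10)

    def test_parseval_with_unit_weights(self, rng):
        T = 7
        x = rng.standard_normal((T, 4))
        C, S = dft_matrices(T)
        spec_energy = ((x.T @ C) ** 2 + (x.T @ S) ** 2).sum()
        assert spec_energy / T == pytest.approx((x ** 2).sum(), rel=1e-6)
        # and the identity-configured block conserves the signal exactly
        asb = ASB(T, 4).identity_config()
        out = asb_transform(x, asb)
        assert (out ** 2).sum() == pytest.approx((x ** 2).sum(), rel=1e-6)

    def test_high_frequency_boost_is_off_at_zero_and_active_above(self, rng):
        T = 7
        x = rng.standard_normal((T, 2))
        asb = ASB(T, 2, top_k=2)
        asb.res_coeff.data = np.array(0.0)
        asb.boost.data = np.array(0.0)  # (1 + 0) boost: still the identity
        np.testing.assert_allclose(asb_transform(x, asb), x, atol=1e-8)
        asb.boost.data = np.array(0.5)
        boosted = asb_transform(x, asb)
        assert np.max(np.abs(boosted - x)) > 1e-3  # selection engaged


class TestGIFM:
    @staticmethod
    def _tied_gifm(channels=6):
        g = GIFM(channels, 3, nn.seeded_rng(2))
        for i in (1, 2):  # tie all three groups to group 0's weights
            for a, b in zip(g.gateconvs[i].parameters(),
                            g.gateconvs[0].parameters()):
                a.data = b.data.copy()
            for a, b in zip(g.attblocks[i].parameters(),
                            g.attblocks[0].parameters()):
                a.data = b.data.copy()
            g.pools[i].query.data = g.pools[0].query.data.copy()
        return g

    def test_permutation_invariance_with_tied_weights(self, rng):
        g = self._tied_gifm()
        x = rng.standard_normal((7, 6))
        out1 = gifm_fuse(x, x, x, g, gate_override=(0.2, 0.5, 0.3))
        out2 = gifm_fuse(x, x, x, g, gate_override=(0.5, 0.3, 0.2))
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_forced_gates_isolate_group_one(self, rng):
        g = GIFM(6, 3, nn.seeded_rng(3))
        a = rng.standard_normal((7, 6))
        b = rng.standard_normal((7, 6))
        c = rng.standard_normal((7, 6))
        out1 = gifm_fuse(a, b, c, g, gate_override=(1.0, 0.0, 0.0))
        out2 = gifm_fuse(a, b + 5.0, c - 3.0, g, gate_override=(1.0, 0.0, 0.0))
        np.testing.assert_allclose(out1, out2, atol=1e-10)
        # gradient w.r.t. groups 2-3 vanishes
        ta, tb, tc = (Tensor(v, requires_grad=True) for v in (a[None], b[None], c[None]))
        g(ta, tb, tc, gate_override=(1.0, 0.0, 0.0)).sum().backward()
        assert np.all(tb.grad == 0) and np.all(tc.grad == 0)
        assert np.any(ta.grad != 0)

    def test_zero_input_zero_init_trace(self):
        g = GIFM(4, 3, nn.seeded_rng(4))
        for gc in g.gateconvs:
            gc.conv.bias.data[:] = 0.0
            gc.gate.bias.data[:] = 0.0
        for ab in g.attblocks:
            ab.v.bias.data[:] = 0.0
        z = np.zeros((7, 4))
        out = gifm_fuse(z, z, z, g, gate_override=(1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_mismatched_time_axis_rejected(self, rng):
        g = GIFM(4, 3, nn.seeded_rng(5))
        with pytest.raises(ValueError):
            g(Tensor(np.zeros((1, 7, 4))), Tensor(np.zeros((1, 6, 4))),
              Tensor(np.zeros((1, 7, 4))))


class TestMultiScaleCNN:
    def test_equal_logits_is_branch_mean(self, rng):
        ms = MultiScaleCNN(5, (3, 5, 7), nn.seeded_rng(6))
        x = rng.standard_normal((7, 5))
        out = multiscale_cnn(x, ms)
        branches = [b(Tensor(x[None])).mean(axis=1).data[0] for b in ms.branches]
        np.testing.assert_allclose(out, np.mean(branches, axis=0), atol=1e-10)

    def test_dominant_logit_selects_single_branch(self, rng):
        ms = MultiScaleCNN(5, (3, 5, 7), nn.seeded_rng(7))
        ms.logits.data = np.array([50.0, 0.0, 0.0])
        x = rng.standard_normal((7, 5))
        out = multiscale_cnn(x, ms)
        only = ms.branches[0](Tensor(x[None])).mean(axis=1).data[0]
        np.testing.assert_allclose(out, only, atol=1e-8)

    def test_constant_input_gives_constant_branches(self):
        ms = MultiScaleCNN(3, (3, 5), nn.seeded_rng(8))
        x = np.full((7, 3), 2.0)
        for b in ms.branches:
            y = b(Tensor(x[None])).data[0]
            np.testing.assert_allclose(y, np.broadcast_to(y[0], y.shape),
                                       atol=1e-10)
        out = multiscale_cnn(x, ms)
        assert np.isfinite(out).all()


class TestFullModel:
    def test_identical_records_identical_predictions(self, small_dataset):
        records, _ = small_dataset
        model = APYieldNet(APYieldNetConfig(seed=0))
        model.scaler = DataScaler.fit(records)
        p = model.predict_records([records[0], records[0].copy()])
        assert p[0] == p[1]
        assert np.isfinite(p).all()

    def test_forward_is_finite_scalar_per_record(self, small_dataset):
        records, _ = small_dataset
        model = APYieldNet(APYieldNetConfig(seed=1))
        model.scaler = DataScaler.fit(records)
        val = apyieldnet_forward(records[3], model)
        assert isinstance(val, float) and np.isfinite(val)

    def test_every_parameter_receives_gradient(self, small_dataset):
        records, _ = small_dataset
        model = APYieldNet(APYieldNetConfig(seed=2))
        model.scaler = DataScaler.fit(records)
        t, c, y, a, labels = model.batch_from_records(records[:16])
        pred = model.forward(t, c, y, a)
        nn.mse_loss(pred, (labels - labels.mean()) / labels.std()).backward()
        dead = [p.shape for p in model.parameters()
                if p.grad is None or np.all(p.grad == 0)]
        assert dead == []
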