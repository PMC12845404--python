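"""Detection feature blocks: identity limits, equation contracts, and a
tiny end-to-end blob-detection smoke test."""

import numpy as np
import pytest
from scipy.ndimage import maximum_filter

from apyield import nn
from apyield.autodiff import Tensor
from apyield.detectblocks import (FMA, FSPPF, GLICM, IAFM, SHSA, SS2D,
                                  ConvAttn, channel_shuffle, convattn,
                                  fma_modulate, fsppf_forward, glicm_forward,
                                  iafm_fuse, shsa, ss2d_scan, zero_biases)
from apyield.synthdata import generate_feature_maps


class TestSS2D:
    def test_hand_unrolled_recurrence_on_1x3_row(self):
        """A = 0.5, B = C = 1, D = 0, input [1, 0, 0] -> [1, 0.5, 0.25]."""
        ss = SS2D(1, 1, nn.seeded_rng(0))
        d = ss.dirs[0]
        d.A.data[:] = 0.5
        d.B.data[:] = 1.0
        d.C.data[:] = 1.0
        d.D.data[:] = 0.0
        seq = Tensor(np.array([[[1.0], [0.0], [0.0]]]))
        out = SS2D._scan(seq, d).data.ravel()
        np.testing.assert_allclose(out, [1.0, 0.5, 0.25])

    def test_pure_skip_identity(self):
        ss = SS2D(3, 4, nn.seeded_rng(1))
        for d in ss.dirs:
            d.A.data[:] = 0.0
            d.C.data[:] = 0.0
            d.D.data[:] = 0.25  # four directions sum to the identity
        x = generate_feature_maps(2, 3, 4, 5, seed=1)
        np.testing.assert_allclose(ss2d_scan(x, ss), x, atol=1e-12)

    def test_degenerate_1x1_spatial(self):
        ss = SS2D(2, 3, nn.seeded_rng(2))
        x = generate_feature_maps(1, 2, 1, 1, seed=2)
        out = ss2d_scan(x, ss)
        manual = sum((x[0, :, 0, 0] @ d.B.data) @ d.C.data
                     + x[0, :, 0, 0] * d.D.data for d in ss.dirs)
        np.testing.assert_allclose(out[0, :, 0, 0], manual, atol=1e-12)

    def test_shape_preserved_and_finite(self):
        ss = SS2D(4, 4, nn.seeded_rng(3))
        x = generate_feature_maps(2, 4, 5, 6, seed=3)
        out = ss2d_scan(x, ss)
        assert out.shape == x.shape and np.isfinite(out).all()


class TestGLICM:
    def test_attention_override_exposes_branch_sum(self):
        g = GLICM(4, nn.seeded_rng(0))
        x = generate_feature_maps(2, 4, 6, 6, seed=4)
        out = glicm_forward(x, g, attention_override=1.0)
        branches = g.local(Tensor(x)).data + g.ss2d(Tensor(x)).data
        np.testing.assert_allclose(out, branches, atol=1e-12)

    def test_shape_contract(self):
        g = GLICM(8, nn.seeded_rng(1), state_dim=4)
        x = generate_feature_maps(2, 8, 16, 16, seed=5)
        assert glicm_forward(x, g).shape == x.shape

    def test_zero_input_zero_bias_trace(self):
        g = zero_biases(GLICM(4, nn.seeded_rng(2)))
        out = glicm_forward(np.zeros((1, 4, 5, 5)), g, attention_override=1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestFMA:
    def test_identity_configuration(self):
        fma = FMA(3, 4, 5).identity_config()
        x = generate_feature_maps(2, 3, 4, 5, seed=6)
        out = fma_modulate(x, fma, gate_override=1.0)
        assert np.max(np.abs(out - x)) < 1e-5

    def test_constant_image_has_dc_only_spectrum(self):
        x = np.full((1, 1, 4, 4), 2.5)
        spec = np.fft.fft2(x[0, 0])
        assert spec[0, 0] == pytest.approx(16 * 2.5)
        assert np.abs(spec).sum() == pytest.approx(np.abs(spec[0, 0]))

    def test_doubling_dc_bin_doubles_mean(self):
        fma = FMA(3, 4, 5).identity_config()
        fma.filter_re.data[:, 0, 0] = 2.0
        x = generate_feature_maps(2, 3, 4, 5, seed=7)
        out = fma_modulate(x, fma, gate_override=1.0)
        np.testing.assert_allclose(out.mean(axis=(2, 3)),
                                   2 * x.mean(axis=(2, 3)), atol=1e-10)


class TestFSPPF:
    def test_equals_plain_sppf_with_identity_fma(self):
        """Independent plain-SPPF oracle built from scipy max filters."""
        rng = nn.seeded_rng(4)
        fs = FSPPF(6, 5, 7, 8, rng)
        x = generate_feature_maps(2, 6, 7, 8, seed=8)
        out = fsppf_forward(x, fs, fma_identity=True)

        def conv1x1(a, w, b):
            return np.einsum("bchw,cd->bdhw", a, w[0, 0]) + b.reshape(1, -1, 1, 1)

        def pool(a):
            return np.stack([[maximum_filter(a[i, c], size=5, mode="constant",
                                             cval=-np.inf)
                              for c in range(a.shape[1])]
                             for i in range(a.shape[0])])

        y = conv1x1(x, fs.conv_in.weight.data, fs.conv_in.bias.data)
        p1 = pool(y)
        p2 = pool(p1)
        p3 = pool(p2)
        ref = conv1x1(np.concatenate([y, p1, p2, p3], axis=1),
                      fs.conv_out.weight.data, fs.conv_out.bias.data)
        assert np.max(np.abs(out - ref)) < 1e-5

    def test_maxpool_stages_pointwise_monotone(self):
        rng = nn.seeded_rng(5)
        fs = FSPPF(4, 4, 6, 6, rng)
        x = Tensor(generate_feature_maps(1, 4, 6, 6, seed=9))
        y = fs.conv_in(x)
        from apyield.autodiff import max_pool2d
        p1 = max_pool2d(y, 5, 2)
        assert np.all(p1.data >= y.data - 1e-12)

    def test_output_shape_as_configured(self):
        fs = FSPPF(8, 12, 5, 5, nn.seeded_rng(6))
        x = generate_feature_maps(3, 8, 5, 5, seed=10)
        assert fsppf_forward(x, fs).shape == (3, 12, 5, 5)


class TestIAFMSubOperators:
    def test_channel_shuffle_double_application_identity(self):
        x = generate_feature_maps(1, 8, 2, 2, seed=11)
        assert np.array_equal(channel_shuffle(channel_shuffle(x, 2), 4), x)

    def test_channel_shuffle_preserves_value_multiset(self):
        x = generate_feature_maps(1, 6, 3, 3, seed=12)
        out = channel_shuffle(x, 3)
        assert sorted(x.ravel()) == sorted(out.ravel())

    def test_channel_shuffle_indivisible_rejected(self):
        with pytest.raises(ValueError):
            channel_shuffle(np.zeros((1, 6, 2, 2)), 4)

    def test_shsa_uniform_attention_is_spatial_mean(self):
        sh = SHSA(4, nn.seeded_rng(7))
        x = generate_feature_maps(1, 4, 3, 3, seed=13)
        out = shsa(x, sh, uniform_attention=True, identity_value=True)
        np.testing.assert_allclose(out, x.mean(axis=(2, 3), keepdims=True)
                                   * np.ones_like(x), atol=1e-12)

    def test_convattn_all_ones_modulation_is_pointwise_projection(self):
        ca = ConvAttn(4, nn.seeded_rng(8))
        x = generate_feature_maps(1, 4, 3, 3, seed=14)
        out = convattn(x, ca, modulation_override=1.0)
        ref = (np.einsum("bchw,cd->bdhw", x, ca.pw.weight.data[0, 0])
               + ca.pw.bias.data.reshape(1, -1, 1, 1))
        np.testing.assert_allclose(out, ref, atol=1e-12)


class TestIAFM:
    def test_concat_channel_count_is_sum_of_parts(self):
        ia = IAFM(4, 6, nn.seeded_rng(9))
        x1 = Tensor(generate_feature_maps(2, 4, 5, 5, seed=15))
        x2 = Tensor(generate_feature_maps(2, 4, 5, 5, seed=16))
        x1p, x2p, xt, xs, xc = ia.parts(x1, x2)
        assert xc.shape[1] == (x1p.shape[1] + x2p.shape[1]
                               + xt.shape[1] + xs.shape[1])

    def test_equal_inputs_tied_convattn_squares_elementwise(self):
        ia = IAFM(4, 6, nn.seeded_rng(10), tie_convattn=True)
        x = Tensor(generate_feature_maps(2, 4, 5, 5, seed=17))
        x1p, _, _, xs, _ = ia.parts(x, x)
        assert np.array_equal(xs.data, x1p.data ** 2)  # exact

    def test_zero_inputs_zero_init_trace(self):
        ia = zero_biases(IAFM(4, 6, nn.seeded_rng(11)))
        z = Tensor(np.zeros((1, 4, 5, 5)))
        _, _, _, xs, _ = ia.parts(z, z)
        np.testing.assert_array_equal(xs.data, 0.0)
        out = ia(z, Tensor(np.zeros((1, 4, 5, 5)))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_spatial_mismatch_rejected_no_implicit_resize(self):
        ia = IAFM(4, 6, nn.seeded_rng(12))
        with pytest.raises(ValueError):
            ia(Tensor(np.zeros((1, 4, 5, 5))), Tensor(np.zeros((1, 4, 6, 6))))

    def test_finite_in_finite_out_and_gradient_reach(self):
        ia = IAFM(4, 6, nn.seeded_rng(13))
        x1 = Tensor(generate_feature_maps(2, 4, 5, 5, seed=18), requires_grad=True)
        x2 = Tensor(generate_feature_maps(2, 4, 5, 5, seed=19), requires_grad=True)
        out = ia(x1, x2)
        assert np.isfinite(out.data).all()
        out.sum().backward()
        dead = [p.shape for p in ia.parameters()
                if p.grad is None or np.all(p.grad == 0)]
        assert dead == []


# ---------------------------------------------------------------------------
# toy end-to-end detector

def _make_blobs(n, size, rng):
    imgs = np.zeros((n, 1, size, size))
    boxes = []
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        cx, cy = rng.uniform(3, size - 3, 2)
        r = rng.uniform(1.5, 3.0)
        imgs[i, 0] = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)
                              / (2 * (r / 1.5) ** 2)))
        boxes.append((cx, cy, 2 * r, 2 * r))
    return imgs, boxes


class _ToyDetector(nn.Module):
    """Single-scale grid detector built from the three blocks under test."""

    def __init__(self, seed=0):
        super().__init__()
        rng = nn.seeded_rng(seed)
        self.stem = nn.Conv2d(1, 8, 3, rng, stride=2)
        self.glicm = GLICM(8, rng, state_dim=4)
        self.fsppf = FSPPF(8, 8, 8, 8, rng)
        self.iafm = IAFM(8, 8, rng, convattn_kernel=3)
        self.head = nn.Conv2d(8, 5, 1, rng)

    def forward(self, x):
        f1 = self.glicm(self.stem(x))
        f2 = self.fsppf(f1)
        return self.head(self.iafm(f1, f2))


def _loss(out, boxes, size, grid):
    cell = size / grid
    b = out.shape[0]
    tobj = np.zeros((b, grid, grid))
    pos, tbox = [], np.zeros((b, 4))
    for i, (cx, cy, w, h) in enumerate(boxes):
        gi, gj = int(cy // cell), int(cx // cell)
        tobj[i, gi, gj] = 1.0
        pos.append((i, gi, gj))
        tbox[i] = [cx / cell - gj, cy / cell - gi,
                   np.log(w / cell), np.log(h / cell)]
    z = out[:, 0, :, :]
    obj_loss = (((1.0 + z.exp()).log()) - Tensor(tobj) * z).mean()
    box_loss = None
    for i, gi, gj in pos:
        t = ((out[i, 1:5, gi, gj] - Tensor(tbox[i])) ** 2).mean()
        box_loss = t if box_loss is None else box_loss + t
    return obj_loss * 2.0 + box_loss * (1.0 / len(pos))


def _iou(a, b):
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter + 1e-9)


def _map50(out, boxes, size, grid, conf=0.2):
    cell = size / grid
    dets = []
    for i in range(out.shape[0]):
        obj = 1.0 / (1.0 + np.exp(-out[i, 0]))
        for gi in range(grid):
            for gj in range(grid):
                if obj[gi, gj] < conf:
                    continue
                dx, dy, lw, lh = out[i, 1:5, gi, gj]
                dets.append((i, obj[gi, gj], (gj + dx) * cell,
                             (gi + dy) * cell, np.exp(lw) * cell,
                             np.exp(lh) * cell))
    dets.sort(key=lambda d: -d[1])
    matched, tps = set(), []
    for d in dets:
        if d[0] not in matched and _iou(d[2:], boxes[d[0]]) >= 0.5:
            matched.add(d[0])
            tps.append(1)
        else:
            tps.append(0)
    if not tps:
        return 0.0
    tps = np.array(tps)
    cum = np.cumsum(tps)
    prec = cum / (np.arange(len(tps)) + 1)
    rec = cum / len(boxes)
    return sum((prec[rec >= r].max() if np.any(rec >= r) else 0.0)
               for r in np.linspace(0, 1, 11)) / 11


@pytest.mark.timeout(600)
def test_toy_detector_overfits_synthetic_blobs():
    """GLICM + F-SPPF + IAFM trained end to end localize single gaussian
    blobs on a coarse grid with training mAP50 >= 0.9 (seeded)."""
    rng = np.random.default_rng(42)
    imgs, boxes = _make_blobs(12, 16, rng)
    model = _ToyDetector(seed=0)
    opt = nn.Adam(model.parameters(), lr=3e-3)
    x = Tensor(imgs)
    for _ in range(300):
        opt.zero_grad()
        loss = _loss(model(x), boxes, 16, 8)
        loss.backward()
        opt.step()
    model.eval()
    ap = _map50(model(x).data, boxes, 16, 8)
    assert ap >= 0.9
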