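"""The fusion and contact-prototype layers against independent oracles.

The scalar-loop reference implementations here recompute every step of the
prototype (cosine, clamping, threshold filters, weighted aggregation, score)
with explicit Python loops, sharing no code with the vectorized pipeline.
"""

import math

import numpy as np
import pytest

from tcrcontact.autodiff import Tensor, parameter
from tcrcontact.layers import (AttentionParams, ThresholdBank, aggregate_area,
                               bce_loss, contact_filter, contact_prototype,
                               contact_score, cross_attend, fuse, layer_norm,
                               predict, similarity_map)
from tcrcontact.model import ContactHead, HeadConfig


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def loop_prototype(e1, e2, m1, m2, tau, thresholds, n):
    """Scalar-loop reference for the full prototype f (Eqs. of the head)."""
    B, N, _ = e1.shape
    weights = np.exp(thresholds) / np.exp(thresholds).sum()
    S = np.zeros((B, N, N))
    A = np.zeros((B, N, N))
    w = np.zeros(B)
    for b in range(B):
        for i in range(N):
            for j in range(N):
                if m1[b, i] == 0 or m2[b, j] == 0:
                    continue
                ni = math.sqrt((e1[b, i] ** 2).sum() + 1e-12)
                nj = math.sqrt((e2[b, j] ** 2).sum() + 1e-12)
                cos = float(e1[b, i] @ e2[b, j]) / (ni * nj)
                S[b, i, j] = min(max(cos, 0.0), 1.0) / max(tau, 1.0)
                acc = 0.0
                for t, a in zip(thresholds, weights):
                    acc += a * sigmoid((S[b, i, j] - t) * n)
                A[b, i, j] = acc / len(thresholds)
        w[b] = A[b].sum() / n ** 2
    return S, A, w


def run_prototype(e1, e2, m1, m2, tau=1.0, n_thresholds=10, n=None):
    bank = ThresholdBank.evenly_spaced(n_thresholds)
    cm = contact_prototype(Tensor(e1), Tensor(e2), Tensor(tau), bank,
                           m1, m2, n=n)
    return bank, cm


class TestSimilarity:
    def test_self_similarity_diagonal_is_one(self, rng):
        e = rng.normal(size=(1, 4, 6))
        m = np.ones((1, 4))
        s = similarity_map(Tensor(e), Tensor(e), Tensor(1.0), m, m)
        np.testing.assert_allclose(np.diagonal(s.data[0]), 1.0, rtol=1e-9)

    def test_orthogonal_and_antiparallel_rows_read_zero(self):
        e1 = np.array([[[1.0, 0.0], [1.0, 0.0]]])
        e2 = np.array([[[0.0, 1.0], [-1.0, 0.0]]])
        m = np.ones((1, 2))
        s = similarity_map(Tensor(e1), Tensor(e2), Tensor(1.0), m, m)
        np.testing.assert_allclose(s.data[0, :, 0], 0.0, atol=1e-12)  # orthogonal
        np.testing.assert_allclose(s.data[0, :, 1], 0.0, atol=1e-12)  # cos = −1
    def test_zero_norm_valid_row_gives_zero_not_error(self):
        e1 = np.array([[[0.0, 0.0], [1.0, 0.0]]])
        e2 = np.array([[[1.0, 0.0], [1.0, 0.0]]])
        m = np.ones((1, 2))
        s = similarity_map(Tensor(e1), Tensor(e2), Tensor(1.0), m, m)
        np.testing.assert_allclose(s.data[0, 0], 0.0, atol=1e-6)

    def test_temperature_below_one_does_not_inflate_range(self, rng):
        e = rng.normal(size=(1, 3, 4))
        m = np.ones((1, 3))
        s = similarity_map(Tensor(e), Tensor(e), Tensor(0.25), m, m)
        assert s.data.max() <= 1.0 + 1e-12


class TestFilterAndArea:
    def test_filter_is_half_at_threshold_and_saturates(self):
        s = Tensor(np.array([[0.3, 1.0]]))
        m = contact_filter(s, 0.3, 25)
        assert m.data[0, 0] == pytest.approx(0.5)
        assert m.data[0, 1] == pytest.approx(1.0, abs=1e-7)

    def test_singleton_bank_passes_filter_through(self, rng):
        m1 = Tensor(rng.uniform(size=(3, 3)))
        bank = ThresholdBank(np.array([0.4]))
        np.testing.assert_allclose(aggregate_area([m1], bank).data, m1.data)

    def test_identical_filters_scale_by_inverse_bank_size(self, rng):
        m = Tensor(rng.uniform(size=(3, 3)))
        bank = ThresholdBank.evenly_spaced(4)
        out = aggregate_area([m, m, m, m], bank)
        np.testing.assert_allclose(out.data, m.data / 4, rtol=1e-12)

    def test_three_filters_match_triple_loop_oracle(self, rng):
        bank = ThresholdBank(np.array([0.2, 0.5, 0.7]))
        filters = [Tensor(rng.uniform(size=(4, 4))) for _ in range(3)]
        out = aggregate_area(filters, bank)
        w = np.exp(bank.thresholds) / np.exp(bank.thresholds).sum()
        expect = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expect[i, j] = sum(a * f.data[i, j]
                                   for a, f in zip(w, filters)) / 3
        np.testing.assert_allclose(out.data, expect, rtol=1e-12)

    def test_bank_validation(self):
        with pytest.raises(ValueError):
            ThresholdBank(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            ThresholdBank(np.array([0.5, 1.2]))
        assert ThresholdBank.evenly_spaced(10).area_weights.sum() == \
            pytest.approx(1.0)

    def test_contact_score_arithmetic(self):
        area = np.zeros((1, 5, 5))
        assert contact_score(Tensor(area), 5).data[0] == 0.0
        area[:] = 1.0
        assert contact_score(Tensor(area), 5).data[0] == pytest.approx(1.0)
        area[:] = 0.0
        area[0, 2, 3] = 0.5
        assert contact_score(Tensor(area), 5).data[0] == pytest.approx(0.02)


class TestPrototypeOracle:
    def test_pipeline_matches_scalar_loop_reference(self, rng):
        for _ in range(5):
            e1 = rng.normal(size=(2, 6, 8))
            e2 = rng.normal(size=(2, 6, 8))
            m1 = (rng.uniform(size=(2, 6)) > 0.3).astype(float)
            m2 = (rng.uniform(size=(2, 6)) > 0.3).astype(float)
            m1[:, 0] = 1; m2[:, 0] = 1
            e1 *= m1[..., None]; e2 *= m2[..., None]
            bank, cm = run_prototype(e1, e2, m1, m2, tau=1.3, n=6)
            S, A, w = loop_prototype(e1, e2, m1, m2, 1.3, bank.thresholds, 6)
            np.testing.assert_allclose(cm.similarity.data, S, atol=1e-6)
            np.testing.assert_allclose(cm.area.data, A, atol=1e-6)
            np.testing.assert_allclose(cm.score.data, w, atol=1e-6)

    def test_monotonicity_in_similarity(self, rng):
        e1 = rng.normal(size=(1, 5, 6)); e2 = rng.normal(size=(1, 5, 6))
        m = np.ones((1, 5))
        bank, cm = run_prototype(e1, e2, m, m)
        s = cm.similarity.data.copy()
        bank2 = ThresholdBank.evenly_spaced(10)
        w_weights = bank2.area_weights
        def w_of(smat):
            acc = np.zeros_like(smat)
            for t, a in zip(bank2.thresholds, w_weights):
                acc += a / (1 + np.exp(-(smat - t) * 5))
            return (acc / 10).sum() / 25
        base = w_of(s)
        bumped = s.copy()
        bumped[0, 2, 3] = min(1.0, bumped[0, 2, 3] + 0.2)
        assert w_of(bumped) >= base


class TestCrossAttention:
    def test_single_valid_key_receives_full_weight(self, rng):
        d = 4
        params = AttentionParams.init(d, rng)
        q = rng.normal(size=(1, 3, d))
        kv = rng.normal(size=(1, 3, d))
        qm = np.ones((1, 3))
        km = np.array([[1.0, 0.0, 0.0]])
        out = cross_attend(Tensor(q), qm, Tensor(kv), km, params)
        # with one valid key the context is that key's value row for every
        # query: recompute with the value projection only
        v0 = kv[0, 0] @ params.wv.data + params.bv.data
        ctx = np.tile(v0, (3, 1))
        expect = _ln(q[0] + ctx, params)
        np.testing.assert_allclose(out.data[0], expect, rtol=1e-9)

    def test_all_zero_query_uniform_attention_is_well_defined(self, rng):
        d = 4
        params = AttentionParams.init(d, rng)
        q = np.zeros((1, 2, d))
        kv = rng.normal(size=(1, 3, d))
        out = cross_attend(Tensor(q), np.ones((1, 2)), Tensor(kv),
                           np.ones((1, 3)), params)
        assert np.all(np.isfinite(out.data))
        v = kv[0] @ params.wv.data + params.bv.data
        expect = _ln(np.tile(v.mean(0), (2, 1)), params)
        np.testing.assert_allclose(out.data[0], expect, rtol=1e-9)

    def test_hand_computed_attention_oracle(self, rng):
        d = 4
        params = AttentionParams.init(d, rng)
        q = rng.normal(size=(1, 3, d))
        kv = rng.normal(size=(1, 3, d))
        ones = np.ones((1, 3))
        out = cross_attend(Tensor(q), ones, Tensor(kv), ones, params)
        Q = q[0] @ params.wq.data + params.bq.data
        K = kv[0] @ params.wk.data + params.bk.data
        V = kv[0] @ params.wv.data + params.bv.data
        scores = Q @ K.T / math.sqrt(d)
        attn = np.exp(scores - scores.max(1, keepdims=True))
        attn /= attn.sum(1, keepdims=True)
        expect = _ln(q[0] + attn @ V, params)
        np.testing.assert_allclose(out.data[0], expect, rtol=1e-9)

    def test_dimension_mismatch_raises(self, rng):
        params = AttentionParams.init(4, rng)
        with pytest.raises(ValueError, match="dims differ"):
            cross_attend(Tensor(np.zeros((1, 3, 4))), np.ones((1, 3)),
                         Tensor(np.zeros((1, 3, 5))), np.ones((1, 3)), params)


def _ln(x, params):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + 1e-5) * params.ln_gain.data \
        + params.ln_bias.data


class TestFuse:
    def _blocks(self, rng, B=2, N=7, d=6):
        mk = lambda: rng.normal(size=(B, N, d))
        masks = []
        for _ in range(3):
            m = np.zeros((B, N))
            for b in range(B):
                m[b, :rng.integers(3, N + 1)] = 1.0
            masks.append(m)
        ea, eb, ee = mk(), mk(), mk()
        for e, m in zip((ea, eb, ee), masks):
            e *= m[..., None]
        return (ea, eb, ee), masks

    def test_swap_symmetry_with_tied_weights(self, rng):
        head = ContactHead(HeadConfig(dimension=6, max_length=7, tied=True,
                                      init_seed=3))
        (ea, eb, ee), (ma, mb, me) = self._blocks(rng)
        f1 = fuse(Tensor(ea), Tensor(eb), Tensor(ee), ma, mb, me, head.arrows)
        f2 = fuse(Tensor(eb), Tensor(ea), Tensor(ee), mb, ma, me, head.arrows)
        np.testing.assert_allclose(f1.e_ab.data, f2.e_ba.data, rtol=1e-12)
        np.testing.assert_allclose(f1.e_e_ab.data, f2.e_e_ba.data, rtol=1e-12)
        np.testing.assert_allclose(f1.e_ab_e.data, f2.e_ba_e.data, rtol=1e-12)

    def test_batch_independence(self, rng):
        head = ContactHead(HeadConfig(dimension=6, max_length=7, init_seed=1))
        (ea, eb, ee), (ma, mb, me) = self._blocks(rng, B=4)
        full = fuse(Tensor(ea), Tensor(eb), Tensor(ee), ma, mb, me, head.arrows)
        solo = fuse(Tensor(ea[2:3]), Tensor(eb[2:3]), Tensor(ee[2:3]),
                    ma[2:3], mb[2:3], me[2:3], head.arrows)
        np.testing.assert_allclose(full.e_ab_e.data[2], solo.e_ab_e.data[0],
                                   atol=1e-12)

    def test_padded_peptide_rows_cannot_influence_outputs(self, rng):
        head = ContactHead(HeadConfig(dimension=6, max_length=7, init_seed=2))
        (ea, eb, ee), (ma, mb, me) = self._blocks(rng)
        base = fuse(Tensor(ea), Tensor(eb), Tensor(ee), ma, mb, me, head.arrows)
        ee2 = ee.copy()
        ee2[me == 0] = rng.normal(size=(int((me == 0).sum()), 6)) * 100
        pert = fuse(Tensor(ea), Tensor(eb), Tensor(ee2), ma, mb, me, head.arrows)
        assert np.array_equal(base.e_ab_e.data, pert.e_ab_e.data)
        assert np.array_equal(base.e_e_ab.data, pert.e_e_ab.data)


class TestPredictAndLoss:
    def test_score_average_arithmetic(self, rng):
        head = ContactHead(HeadConfig(dimension=6, max_length=7, init_seed=0))
        (blocks, masks) = TestFuse()._blocks(rng)
        fused = fuse(*[Tensor(b) for b in blocks], *masks, head.arrows)
        y_hat, map_a, map_b = predict(fused, head.tau, head.bank, 7)
        np.testing.assert_allclose(
            y_hat.data, (map_a.score.data + map_b.score.data) / 2, rtol=1e-12)
        assert np.all(y_hat.data >= 0) and np.all(y_hat.data <= 1)

    @pytest.mark.parametrize("y_hat,y,w,expect", [
        (0.5, 1, 1.0, math.log(2)),
        (0.5, 1, 4.0, 4 * math.log(2)),
        (0.5, 0, 4.0, math.log(2)),
    ])
    def test_loss_closed_forms(self, y_hat, y, w, expect):
        loss = bce_loss(Tensor(np.array([y_hat])), np.array([y]), w)
        assert loss.item() == pytest.approx(expect, abs=1e-6)

    def test_batch_loss_matches_scalar_loop(self, rng):
        yh = rng.uniform(0.05, 0.95, size=12)
        y = rng.integers(0, 2, size=12)
        pw = 3.7
        got = bce_loss(Tensor(yh), y, pw).item()
        want = np.mean([-(pw * yi * math.log(pi) + (1 - yi) * math.log(1 - pi))
                        for pi, yi in zip(yh, y)])
        assert got == pytest.approx(want, rel=1e-12)

    def test_loss_requires_positive_weight(self):
        with pytest.raises(ValueError):
            bce_loss(Tensor(np.array([0.5])), np.array([1]), 0.0)

    def test_extreme_scores_are_clamped_to_finite_loss(self):
        loss = bce_loss(Tensor(np.array([0.0, 1.0])), np.array([1, 0]), 1.0)
        assert np.isfinite(loss.item())


class TestGradients:
    def test_finite_difference_gradient_of_loss(self, rng):
        """Autodiff gradients through the whole head match finite differences."""
        head = ContactHead(HeadConfig(dimension=5, max_length=6, dropout=0.0,
                                      init_seed=4))
        head.tau_raw.data = np.asarray(1.0)   # τ ≈ 1.31 > 1: smooth region
        B, N, d = 3, 6, 5
        batch_arrays = {}
        masks = {}
        for key in ("cdr3a", "cdr3b", "peptide"):
            m = np.zeros((B, N))
            for b in range(B):
                m[b, :rng.integers(3, N + 1)] = 1.0
            e = rng.normal(size=(B, N, d)) * m[..., None]
            batch_arrays[key], masks[key] = e, m
        labels = np.array([1.0, 0.0, 1.0])

        class FakeBatch:
            cdr3a = batch_arrays["cdr3a"]; cdr3b = batch_arrays["cdr3b"]
            peptide = batch_arrays["peptide"]
            mask_a = masks["cdr3a"]; mask_b = masks["cdr3b"]
            mask_e = masks["peptide"]; labels_ = labels

        def loss_value():
            y_hat, _, _ = head.forward(FakeBatch)
            return bce_loss(y_hat, labels, 2.0)

        loss = loss_value()
        head.zero_grad()
        loss.backward()
        eps = 1e-5
        for name in ("tau_raw", "e_ba.wq", "ab.wv", "e_ab.ln_gain"):
            t = head.named_parameters()[name]
            flat = t.data.reshape(-1)
            idx = rng.integers(flat.size)
            g = t.grad.reshape(-1)[idx]
            orig = flat[idx]
            flat[idx] = orig + eps
            hi = loss_value().item()
            flat[idx] = orig - eps
            lo = loss_value().item()
            flat[idx] = orig
            fd = (hi - lo) / (2 * eps)
            assert g == pytest.approx(fd, rel=1e-4, abs=1e-9), name


class TestRangeInvariants:
    def test_fuzzed_ranges_and_mask_isolation(self, rng):
        head = ContactHead(HeadConfig(dimension=6, max_length=8, init_seed=6))
        for _ in range(25):
            B = int(rng.integers(1, 4))
            blocks, masks = {}, {}
            for key in ("a", "b", "e"):
                m = np.zeros((B, 8))
                for bi in range(B):
                    m[bi, :rng.integers(1, 9)] = 1.0
                blocks[key] = rng.normal(scale=rng.uniform(0.1, 10),
                                         size=(B, 8, 6)) * m[..., None]
                masks[key] = m

            class FB:
                cdr3a = blocks["a"]; cdr3b = blocks["b"]; peptide = blocks["e"]
                mask_a = masks["a"]; mask_b = masks["b"]; mask_e = masks["e"]

            y_hat, ta, tb = head.forward(FB)
            for arr in (ta.similarity.data, ta.area.data, tb.similarity.data,
                        tb.area.data, ta.filters.data, y_hat.data,
                        ta.score.data, tb.score.data):
                assert np.all(arr >= 0.0) and np.all(arr <= 1.0)
            pair = masks["e"][:, :, None] * masks["b"][:, None, :]
            assert np.all(ta.area.data[pair == 0] == 0.0)
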