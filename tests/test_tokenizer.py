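"""Patchification, attention readout, theta masking and fusion contracts."""

import numpy as np
import pytest

from mfvan import EncoderConfig, TokenizerConfig, encode, fuse_classify, mask_tokens, patchify_and_embed
from mfvan.autodiff import Tensor
from mfvan.tokenizer import (
    FusionHead,
    ScaleOutput,
    ScaleTokenizer,
    TransformerEncoder,
    retained_indices,
)


@pytest.fixture
def rng():
    return np.random.default_rng(21)


class TestConfigs:
    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            TokenizerConfig(s=1)
        with pytest.raises(ValueError):
            EncoderConfig(L=0)
        with pytest.raises(ValueError):
            EncoderConfig(theta=1.0)

    def test_default_theta_is_just_below_uniform(self):
        assert EncoderConfig().resolve_theta(16) == pytest.approx(0.8 / 16)
        assert EncoderConfig(theta=0.2).resolve_theta(16) == 0.2


class TestPatchify:
    def test_tiling_arithmetic(self, rng):
        tok = ScaleTokenizer(channels=3, spatial=32, config=TokenizerConfig(s=4, q=16), rng=rng)
        seq = patchify_and_embed(rng.normal(size=(3, 32, 32)), tok)
        assert seq.tokens.shape == (1, 17, 16)
        assert seq.k == 16

    def test_indivisible_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            ScaleTokenizer(channels=1, spatial=30, config=TokenizerConfig(s=4, q=8), rng=rng)
        tok = ScaleTokenizer(channels=1, spatial=32, config=TokenizerConfig(s=4, q=8), rng=rng)
        with pytest.raises(ValueError):
            patchify_and_embed(rng.normal(size=(1, 30, 30)), tok)

    def test_zero_input_zero_bias_gives_positional_rows(self, rng):
        tok = ScaleTokenizer(channels=1, spatial=8, config=TokenizerConfig(s=2, q=8), rng=rng)
        tok.proj.bias.data[:] = 0.0
        seq = patchify_and_embed(np.zeros((1, 8, 8)), tok)
        np.testing.assert_allclose(seq.tokens.data[0, 1:], tok.pos.data, atol=1e-7)
        np.testing.assert_allclose(seq.tokens.data[0, 0], tok.cls.data[0], atol=1e-7)

    def test_purity(self, rng):
        tok = ScaleTokenizer(channels=2, spatial=16, config=TokenizerConfig(s=4, q=8), rng=rng)
        x = rng.normal(size=(2, 16, 16))
        a = patchify_and_embed(x, tok).tokens.data
        b = patchify_and_embed(x, tok).tokens.data
        np.testing.assert_array_equal(a, b)

    def test_patch_content_routing(self, rng):
        """Each token sees exactly its own patch: zeroing one patch changes one token."""
        tok = ScaleTokenizer(channels=1, spatial=8, config=TokenizerConfig(s=2, q=8), rng=rng)
        x = rng.normal(size=(1, 8, 8))
        base = patchify_and_embed(x, tok).tokens.data[0, 1:]
        x2 = x.copy()
        x2[0, :4, 4:] = 0.0  # patch index 1 (row 0, col 1)
        mod = patchify_and_embed(x2, tok).tokens.data[0, 1:]
        changed = np.abs(mod - base).sum(axis=1) > 1e-9
        assert changed.tolist() == [False, True, False, False]


class TestEncode:
    def _stream(self, rng, enc_cfg, s=3, q=16):
        tok = ScaleTokenizer(channels=1, spatial=12, config=TokenizerConfig(s=s, q=q), rng=rng)
        enc = TransformerEncoder(q, enc_cfg, rng)
        seq = patchify_and_embed(rng.normal(size=(1, 12, 12)), tok)
        return encode(seq, enc)

    def test_patch_weights_normalized_many_inits(self):
        """Weights sum to 1 for 100 random initializations."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = self._stream(rng, EncoderConfig(L=1, heads=2, theta=0.0))
            np.testing.assert_allclose(out.patch_weights.sum(axis=1), 1.0, atol=1e-6)

    def test_theta_zero_retains_everything(self, rng):
        out = self._stream(rng, EncoderConfig(L=2, heads=2, theta=0.0))
        assert [len(r) for r in out.retained] == [out.k]

    def test_identical_keys_give_uniform_attention(self, rng):
        """All-equal patch tokens must receive equal attention weights."""
        q = 8
        tok = ScaleTokenizer(channels=1, spatial=8, config=TokenizerConfig(s=2, q=q), rng=rng)
        tok.pos.data[:] = 0.0  # remove the only source of patch distinctness
        enc = TransformerEncoder(q, EncoderConfig(L=1, heads=1, theta=0.0), rng)
        seq = patchify_and_embed(np.ones((1, 8, 8)), tok)
        out = encode(seq, enc)
        np.testing.assert_allclose(out.patch_weights, 1.0 / out.k, atol=1e-6)


class TestMaskTokens:
    def _out(self, weights):
        w = np.asarray(weights)[None, :]
        return ScaleOutput(
            encoded=Tensor(np.zeros((1, w.shape[1] + 1, 4))),
            patch_weights=w,
            retained=[],
            scale_index=1,
        )

    def test_direct_threshold(self):
        out = mask_tokens(self._out([0.5, 0.3, 0.2]), 0.4)
        assert out.retained[0].tolist() == [0]

    def test_tie_at_theta_is_retained(self):
        out = mask_tokens(self._out([0.5, 0.3, 0.2]), 0.3)
        assert out.retained[0].tolist() == [0, 1]

    def test_theta_zero_drops_nothing(self):
        out = mask_tokens(self._out([0.5, 0.3, 0.2]), 0.0)
        assert out.retained[0].tolist() == [0, 1, 2]

    def test_argmax_fallback_when_all_below(self):
        out = mask_tokens(self._out([0.2, 0.5, 0.3]), 0.9)
        assert out.retained[0].tolist() == [1]

    def test_fallback_tie_break_lowest_index(self):
        out = mask_tokens(self._out([0.25, 0.25, 0.25, 0.25]), 0.5)
        assert out.retained[0].tolist() == [0]

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            mask_tokens(self._out([1.0]), 1.2)

    def test_brute_force_scan_random_vectors(self):
        """Retained set == {j : w_j >= theta} (or argmax) on 1000 random draws."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            k = int(rng.integers(2, 20))
            w = rng.dirichlet(np.ones(k))
            theta = float(rng.uniform(0, 0.8))
            got = retained_indices(w, theta).tolist()
            expect = [j for j in range(k) if w[j] >= theta]
            if not expect:
                expect = [int(np.argmax(w))]
            assert got == expect


class TestFuseClassify:
    def _outputs(self, rng, n=2, q=8, k=4, retained=None):
        outs = []
        for i in range(n):
            enc = Tensor(rng.normal(size=(1, k + 1, q)))
            w = rng.dirichlet(np.ones(k))[None, :]
            keep = np.arange(k) if retained is None else np.asarray(retained)
            outs.append(
                ScaleOutput(encoded=enc, patch_weights=w, retained=[keep], scale_index=i + 1)
            )
        return outs

    def test_probabilities_normalized(self, rng):
        outs = self._outputs(rng, n=3)
        head = FusionHead(q=8, n_classes=3, n_streams=3, rng=rng)
        fused = fuse_classify(outs, head)
        np.testing.assert_allclose(fused.p.data.sum(axis=1), 1.0, atol=1e-6)
        for ps in fused.p_scale:
            np.testing.assert_allclose(ps.data.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_pooled_vectors_average_to_themselves(self, rng):
        outs = self._outputs(rng, n=1)
        triple = [outs[0], outs[0], outs[0]]
        head = FusionHead(q=8, n_classes=3, n_streams=3, rng=rng)
        single_head = FusionHead(q=8, n_classes=3, n_streams=1, rng=np.random.default_rng(21))
        # same fusion MLP weights: copy
        single_head.fc1, single_head.fc2 = head.fc1, head.fc2
        p3 = fuse_classify(triple, head).p.data
        p1 = fuse_classify(outs, single_head).p.data
        np.testing.assert_allclose(p3, p1, atol=1e-6)

    def test_retained_order_permutation_invariance(self, rng):
        outs = self._outputs(rng, n=2, retained=[2, 0, 3])
        head = FusionHead(q=8, n_classes=3, n_streams=2, rng=rng)
        p_a = fuse_classify(outs, head).p.data
        for o in outs:
            o.retained = [np.array([3, 2, 0])]
        p_b = fuse_classify(outs, head).p.data
        np.testing.assert_allclose(p_a, p_b, atol=1e-12)

    def test_masked_tokens_do_not_affect_output(self, rng):
        """Dropped tokens are truly excluded: changing them leaves p unchanged."""
        outs = self._outputs(rng, n=1, retained=[0, 2])
        head = FusionHead(q=8, n_classes=2, n_streams=1, rng=rng)
        p_before = fuse_classify(outs, head).p.data.copy()
        outs[0].encoded.data[0, 2, :] = 999.0  # token index 1 (patch 1) is masked
        p_after = fuse_classify(outs, head).p.data
        np.testing.assert_allclose(p_before, p_after, atol=1e-12)

    def test_empty_input_rejected(self, rng):
        head = FusionHead(q=8, n_classes=2, n_streams=1, rng=rng)
        with pytest.raises(ValueError):
            fuse_classify([], head)
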