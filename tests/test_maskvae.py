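"""Masked-input VAE: masking contract, posterior heads, reparameterization,
decoder, and loss terms (with a Monte-Carlo KL oracle and a numerical
gradient check of the full objective)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgrecon.maskvae import (
    LeadMask,
    ModelConfig,
    VaeModel,
    kl_divergence,
    mask_leads,
    pad_to_multiple,
    recon_loss,
    reconstruct,
    reparameterize,
    total_loss,
)
from ecgrecon.nn import Tensor


class TestLeadMask:
    def test_retained_indices_for_main_configuration(self, mask3):
        np.testing.assert_array_equal(mask3.retained_indices, [1, 6, 10])
        assert mask3.retained_names == ("II", "V1", "V5")

    def test_all_retained_or_all_dropped_rejected(self):
        with pytest.raises(ValueError):
            LeadMask(np.zeros(12))
        with pytest.raises(ValueError):
            LeadMask(np.ones(12))


class TestMaskLeads:
    def test_retained_rows_pass_and_dropped_rows_zero(self, mask3):
        x = np.ones((12, 4))
        out = mask_leads(x, mask3)
        for i in (1, 6, 10):
            np.testing.assert_array_equal(out[i], 1.0)
        dropped = [i for i in range(12) if i not in (1, 6, 10)]
        assert np.all(out[dropped] == 0.0)

    def test_zero_input_stays_zero(self, mask3):
        assert np.all(mask_leads(np.zeros((12, 7)), mask3) == 0.0)

    def test_wrong_lead_count_rejected(self, mask3):
        with pytest.raises(ValueError):
            mask_leads(np.zeros((11, 4)), mask3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 12 - 2), st.integers(0, 10 ** 6))
    def test_masking_is_idempotent(self, flags_int, data_seed):
        flags = np.array([(flags_int >> i) & 1 for i in range(12)])
        if flags.sum() in (0, 12):
            flags[0] = 1 - flags[0]
        mask = LeadMask(flags)
        x = np.random.default_rng(data_seed).standard_normal((12, 16))
        once = mask_leads(x, mask)
        np.testing.assert_array_equal(mask_leads(once, mask), once)


class TestEncode:
    def test_posterior_shapes_and_grid_width(self, tiny_model, mask3):
        x = np.random.default_rng(0).standard_normal((12, 64))
        mu, lv = tiny_model.encode(mask_leads(x, mask3))
        assert mu.shape == (64 // tiny_model.config.down_factor, 4)
        assert lv.shape == mu.shape

    def test_downsample_arithmetic(self):
        assert ModelConfig(n_down_stages=3).down_factor == 8
        assert 1024 // ModelConfig(n_down_stages=3).down_factor == 128

    def test_indivisible_length_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(np.zeros((12, 63)))

    def test_deterministic_given_parameters(self, tiny_model):
        x = np.random.default_rng(1).standard_normal((12, 64))
        a = tiny_model.encode(x)
        b = tiny_model.encode(x)
        np.testing.assert_array_equal(a[0], b[0])

    def test_zeroed_heads_give_zero_posterior_parameters(self, tiny_model):
        tiny_model.mu_head.weight.data[...] = 0.0
        tiny_model.mu_head.bias.data[...] = 0.0
        tiny_model.logvar_head.weight.data[...] = 0.0
        tiny_model.logvar_head.bias.data[...] = 0.0
        mu, lv = tiny_model.encode(np.random.default_rng(2).standard_normal((12, 64)))
        np.testing.assert_array_equal(mu, 0.0)
        np.testing.assert_array_equal(lv, 0.0)


class TestReparameterize:
    def test_sigma_to_zero_limit_collapses_to_mu(self):
        mu = np.random.default_rng(0).standard_normal((8, 4))
        state = reparameterize(mu, np.full((8, 4), -50.0), seed=1)
        assert np.max(np.abs(state.z - mu)) < 1e-10

    def test_monte_carlo_moments_of_standard_draw(self):
        state = reparameterize(np.zeros(10 ** 5), np.zeros(10 ** 5), seed=2)
        assert abs(state.z.mean()) < 0.02
        assert abs(state.z.var() - 1.0) < 0.05

    def test_fixed_seed_reproduces_eps(self):
        mu, lv = np.zeros((4, 4)), np.zeros((4, 4))
        a = reparameterize(mu, lv, seed=3)
        b = reparameterize(mu, lv, seed=3)
        np.testing.assert_array_equal(a.eps, b.eps)

    def test_latent_state_invariant_holds(self):
        rng = np.random.default_rng(4)
        state = reparameterize(rng.standard_normal((6, 4)),
                               rng.standard_normal((6, 4)), seed=5)
        np.testing.assert_allclose(
            state.z, state.mu + np.exp(state.log_var / 2) * state.eps)


class TestDecode:
    def test_round_trip_shape_preserved(self, tiny_model, mask3):
        for T in (32, 64, 128):
            x = np.random.default_rng(0).standard_normal((12, T))
            mu, _ = tiny_model.encode(mask_leads(x, mask3))
            out = tiny_model.decode(mu)
            assert out.shape == (12, T)

    def test_deterministic(self, tiny_model):
        z = np.random.default_rng(1).standard_normal((16, 4))
        np.testing.assert_array_equal(tiny_model.decode(z), tiny_model.decode(z))

    def test_attention_on_constant_sequence_is_constant(self, tiny_model):
        # constant keys: softmax weights are uniform, output = value everywhere
        attn = tiny_model.attn
        C = tiny_model.config.bottleneck_channels
        h = Tensor(np.tile(np.random.default_rng(2).standard_normal((1, C, 1)),
                           (1, 1, 16)))
        out = attn(h).data
        assert np.ptp(out, axis=2).max() < 1e-10

    def test_wrong_latent_width_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.decode(np.zeros((16, 5)))


class TestPadToMultiple:
    def test_pad_and_identity_cases(self):
        x = np.arange(24, dtype=float).reshape(2, 12)[None]
        padded, (lo, hi) = pad_to_multiple(x, 8)
        assert padded.shape[-1] == 16 and (lo, hi) == (2, 2)
        same, (lo0, hi0) = pad_to_multiple(x[..., :8], 8)
        assert (lo0, hi0) == (0, 0)

    def test_reconstruct_crops_back_to_input_length(self, tiny_model, mask3):
        x = np.random.default_rng(3).standard_normal((12, 100))
        out = reconstruct(tiny_model, x, mask3)
        assert out.shape == (12, 100)

    def test_passthrough_copies_retained_leads(self, tiny_model, mask3):
        x = np.random.default_rng(4).standard_normal((12, 64))
        out = reconstruct(tiny_model, x, mask3, passthrough=True)
        np.testing.assert_array_equal(out[[1, 6, 10]], x[[1, 6, 10]])


class TestReconLoss:
    def test_zero_iff_equal_and_unit_difference(self):
        x = np.random.default_rng(0).standard_normal((12, 8))
        assert recon_loss(x, x) == 0.0
        assert recon_loss(x, x + 1.0) == pytest.approx(1.0)

    def test_two_element_example(self):
        assert recon_loss(np.array([0.0, 0.0]), np.array([0.0, 2.0])) == 2.0

    def test_sum_per_sample_reduction_scales_by_elements(self):
        x = np.zeros((2, 12, 8))
        y = np.ones((2, 12, 8))
        assert recon_loss(x, y, reduction="sum_per_sample") == pytest.approx(96.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recon_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestKlDivergence:
    def test_posterior_equal_prior_gives_zero(self):
        assert kl_divergence(np.zeros((8, 4)), np.zeros((8, 4))) == 0.0

    def test_unit_mean_single_coordinate_gives_half(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            assert kl_divergence(rng.standard_normal((6, 4)),
                                 rng.standard_normal((6, 4))) >= 0.0

    def test_matches_monte_carlo_oracle_within_one_percent(self):
        rng = np.random.default_rng(6)
        mc_rng = np.random.default_rng(7)
        for _ in range(5):
            mu = rng.uniform(-1.5, 1.5, size=4)
            lv = rng.uniform(-1.0, 1.0, size=4)
            sigma = np.exp(lv / 2)
            z = mu + sigma * mc_rng.standard_normal((10 ** 6, 4))
            log_q = -0.5 * (((z - mu) / sigma) ** 2 + lv + np.log(2 * np.pi)).sum(1)
            log_p = -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(1)
            mc = float(np.mean(log_q - log_p))
            closed = kl_divergence(mu, lv)
            assert abs(closed - mc) / closed < 0.01


class TestTotalLoss:
    def test_beta_zero_reduces_to_recon(self):
        x = np.random.default_rng(0).standard_normal((12, 8))
        y = x + 0.1
        total, comps = total_loss(x, y, np.ones((2, 4)), np.zeros((2, 4)), beta=0.0)
        assert total == comps["recon"]

    def test_perfect_reconstruction_and_prior_gives_zero(self):
        x = np.zeros((12, 8))
        total, _ = total_loss(x, x, np.zeros((2, 4)), np.zeros((2, 4)))
        assert total == 0.0

    def test_component_arithmetic(self):
        x = np.zeros((1, 1))
        y = np.full((1, 1), 0.1)  # recon = 0.01
        mu = np.array([[2.0]])    # kl = 2.0
        total, comps = total_loss(x, y, mu, np.zeros((1, 1)), beta=1e-4)
        assert comps["recon"] == pytest.approx(0.01)
        assert comps["kl"] == pytest.approx(2.0)
        assert total == pytest.approx(0.0102)

    def test_perceptual_weight_without_embedder_rejected(self):
        x = np.zeros((12, 8))
        with pytest.raises(ValueError):
            total_loss(x, x, np.zeros((2, 4)), np.zeros((2, 4)),
                       perceptual_weight=0.5)

    def test_perceptual_term_uses_embedder_features(self):
        x = np.zeros((12, 8))
        y = np.ones((12, 8))
        emb = lambda s: np.asarray(s, float).mean(axis=1)
        total, comps = total_loss(x, y, np.zeros((2, 4)), np.zeros((2, 4)),
                                  beta=0.0, perceptual_weight=2.0, embedder=emb)
        assert comps["perceptual"] == pytest.approx(1.0)
        assert total == pytest.approx(comps["recon"] + 2.0)


def test_full_objective_gradient_check(tiny_model, mask3):
    """Analytic gradients of the ELBO agree with central differences."""
    from ecgrecon.training import _batch_loss
    x = np.random.default_rng(10).standard_normal((2, 12, 32))
    rng_idx = np.random.default_rng(11)

    def value():
        total, _, _ = _batch_loss(tiny_model, x, mask3, 1e-4,
                                  np.random.default_rng(99))
        return total

    loss = value()
    loss.backward()
    params = tiny_model.parameters()
    for pi in rng_idx.choice(len(params), size=6, replace=False):
        p = params[pi]
        idx = tuple(np.unravel_index(rng_idx.integers(p.data.size), p.data.shape))
        analytic = p.grad[idx]
        eps = 1e-6
        orig = p.data[idx]
        p.data[idx] = orig + eps
        up = value().item()
        p.data[idx] = orig - eps
        down = value().item()
        p.data[idx] = orig
        numeric = (up - down) / (2 * eps)
        scale = max(abs(numeric), abs(analytic), 1e-6)
        assert abs(numeric - analytic) / scale < 1e-4


def test_tiny_model_can_fit_one_batch():
    """Capacity sanity: a few high-lr steps cut the loss on a fixed batch."""
    from ecgrecon.nn import AdamW
    from ecgrecon.training import _batch_loss
    cfg = ModelConfig(base_channels=8, bottleneck_channels=16, n_down_stages=2,
                      latent_dim=4, attention_heads=4, groupnorm_groups=4,
                      residual_blocks_per_stage=1)
    model = VaeModel(cfg, seed=0)
    mask = LeadMask.from_retained("II,V1,V5")
    x = np.random.default_rng(0).standard_normal((4, 12, 32)).astype(np.float32)
    opt = AdamW(model.parameters(), lr=3e-3)
    losses = []
    for _ in range(40):
        model.zero_grad()
        total, _, _ = _batch_loss(model, x, mask, 0.0, np.random.default_rng(1))
        total.backward()
        opt.step()
        losses.append(float(total.data))
    assert losses[-1] < 0.5 * losses[0]
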