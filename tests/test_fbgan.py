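"""Generator/discriminator architecture contracts and adversarial training."""

import numpy as np
import pytest

from mieeg import nn
from mieeg.cspselect import SparseSpatialFilter
from mieeg.fbgan import (DiscriminatorSpec, Discriminator, GANOptimizers,
                         GANTrainingConfig, GeneratorSpec, SparseProjection,
                         _var_kernel, build_discriminator, build_generator,
                         gan_step, generate, load_checkpoint, save_checkpoint,
                         train_fbgan)


class TestGeneratorSpec:
    def test_default_roster_matches_reference_table(self):
        spec = GeneratorSpec.default()
        assert spec.noise_dim == 1600
        assert spec.fc_out == 256_000
        kernels = [ly.kernel for ly in spec.layers]
        strides = [ly.stride for ly in spec.layers]
        channels = [(ly.in_channels, ly.out_channels) for ly in spec.layers]
        assert kernels == [(3, 15), (3, 15), (3, 5), (4, 5), (1, 2)]
        assert strides == [(1, 3), (1, 3), (1, 2), (2, 1), (1, 1)]
        assert channels == [(128, 128), (128, 128), (128, 64), (64, 32), (32, 1)]
        assert [ly.batchnorm for ly in spec.layers] == [True] * 4 + [False]

    def test_shape_trace_ends_on_22x1000(self):
        assert GeneratorSpec.default().shape_trace()[-1] == (22, 1000)

    def test_inconsistent_spec_reports_trace(self):
        spec = GeneratorSpec.default()
        bad = GeneratorSpec(noise_dim=spec.noise_dim, fc_out=spec.fc_out,
                            lattice=spec.lattice, layers=spec.layers,
                            output_shape=(22, 999))
        with pytest.raises(ValueError, match="shape trace"):
            build_generator(bad)


class TestSmallGenerator:
    def test_small_spec_forward_shape(self):
        gen = build_generator(GeneratorSpec.small(8, 64, noise_dim=16), seed=0)
        z = np.zeros((3, 16), dtype=np.float32)
        assert gen(z).shape == (3, 1, 8, 64)

    def test_inference_mode_is_deterministic(self):
        gen = build_generator(GeneratorSpec.small(6, 32, noise_dim=8), seed=1)
        z = np.random.default_rng(2).standard_normal((4, 8)).astype(np.float32)
        gen.eval()
        np.testing.assert_array_equal(gen(z), gen(z))


class TestDiscriminators:
    def test_raw_feature_count_is_750(self):
        assert DiscriminatorSpec.raw_default().feature_count() == 750

    def test_fb_feature_count_is_750(self):
        assert DiscriminatorSpec.fb_default(16).feature_count() == 750

    def test_var_rule_collapses_rows(self):
        assert _var_kernel(16) == 4
        assert _var_kernel(20) == 5
        assert _var_kernel(16) != _var_kernel(20)

    def test_raw_scalar_score(self, rng):
        d = build_discriminator("raw", seed=0)
        x = rng.standard_normal((2, 1, 22, 1000)).astype(np.float32)
        assert d(x).shape == (2, 1)

    @pytest.mark.parametrize("n_sel", [16, 17])
    def test_fb_scalar_score(self, rng, n_sel):
        d = build_discriminator("fb", n_sel=n_sel, seed=0)
        x = rng.standard_normal((2, 1, n_sel, 1000)).astype(np.float32)
        assert d(x).shape == (2, 1)

    def test_fb_needs_four_rows(self):
        with pytest.raises(ValueError, match="n_sel"):
            build_discriminator("fb", n_sel=3)


def _small_setup(seed=0, C=6, T=64, n_sel=4):
    rng = np.random.default_rng(seed)
    gen = build_generator(GeneratorSpec.small(C, T, noise_dim=8), seed=seed)
    d_raw = Discriminator(DiscriminatorSpec.small("raw", C, T),
                          np.random.default_rng(seed + 1))
    d_fb = Discriminator(DiscriminatorSpec.small("fb", n_sel, T),
                         np.random.default_rng(seed + 2))
    Wm, _ = np.linalg.qr(rng.standard_normal((C, n_sel)))
    W = SparseSpatialFilter(W=Wm, provenance=[(0, 1, k) for k in range(n_sel)],
                            band_of_column=np.zeros(n_sel, dtype=int))
    proj = SparseProjection(W, fs=64.0, n_samples=T, bands=((2.0, 28.0),))
    return gen, d_raw, d_fb, proj, rng


class TestGanStep:
    def test_chance_level_loss_at_score_half(self):
        gen, d_raw, d_fb, proj, rng = _small_setup()
        # zero the discriminator heads: every score is exactly 0 -> p = 0.5
        for d in (d_raw, d_fb):
            head = d.net.layers[-1]
            head.W.data[...] = 0
            head.b.data[...] = 0
        config = GANTrainingConfig(batch_size=4, lr=1e-12)
        opts = GANOptimizers(gen, d_raw, d_fb, config)
        real = rng.standard_normal((4, 6, 64))
        report = gan_step(gen, d_raw, d_fb, real, proj, config, opts, rng)
        assert report["d_raw"] == pytest.approx(2 * np.log(2), abs=1e-4)
        assert report["d_fb"] == pytest.approx(2 * np.log(2), abs=1e-4)
        assert report["d_total"] == pytest.approx(4 * np.log(2), abs=1e-3)

    def test_fb_weight_zero_isolates_raw_path(self):
        config = GANTrainingConfig(batch_size=4, lr=1e-3, seed=5)

        def run(disc_weights, with_fb):
            gen, d_raw, d_fb, proj, _ = _small_setup(seed=5)
            cfg = GANTrainingConfig(batch_size=4, lr=1e-3, seed=5,
                                    disc_weights=disc_weights)
            opts = GANOptimizers(gen, d_raw, d_fb, cfg)
            rng = np.random.default_rng(99)
            real = np.random.default_rng(7).standard_normal((4, 6, 64))
            gan_step(gen, d_raw, d_fb if with_fb else None, real,
                     proj if with_fb else None, cfg, opts, rng)
            return gen.state_dict()

        s_weighted = run((1.0, 0.0), with_fb=True)
        s_without = run((1.0, 0.0), with_fb=False)
        for k in s_weighted:
            np.testing.assert_array_equal(s_weighted[k], s_without[k])

    def test_discriminator_learns_separable_data(self):
        # real: strong structured signal; fake: small noise -> trivially separable
        d = Discriminator(DiscriminatorSpec.small("raw", 4, 64),
                          np.random.default_rng(0))
        opt = nn.Adam(d.parameters(), lr=1e-3)
        rng = np.random.default_rng(1)
        t = np.arange(64) / 64
        losses = []
        for step in range(50):
            real = (np.sin(2 * np.pi * 4 * t) + 0.1 * rng.standard_normal((5, 4, 64)))
            fake = 0.1 * rng.standard_normal((5, 4, 64))
            d.zero_grad()
            l1, g1 = nn.bce_with_logits(d(real.astype(np.float32)), 1.0)
            d.backward(g1)
            l2, g2 = nn.bce_with_logits(d(fake.astype(np.float32)), 0.0)
            d.backward(g2)
            opt.step()
            losses.append(l1 + l2)
        assert np.mean(losses[-5:]) < 0.5 * np.mean(losses[:5])

    def test_gradient_isolation_between_players(self):
        gen, d_raw, d_fb, proj, rng = _small_setup(seed=3)
        config = GANTrainingConfig(batch_size=3, lr=1e-2)
        opts = GANOptimizers(gen, d_raw, d_fb, config)
        g_before = {k: p.data.copy() for k, p in gen.named_parameters()}
        # discriminator-only half step
        real = rng.standard_normal((3, 6, 64)).astype(np.float32)[:, None]
        fake = gen(rng.standard_normal((3, 8)).astype(np.float32))
        d_raw.zero_grad()
        _, g = nn.bce_with_logits(d_raw(real), 1.0)
        d_raw.backward(g)
        _, g = nn.bce_with_logits(d_raw(fake), 0.0)
        d_raw.backward(g)
        opts.d.step()
        for k, p in gen.named_parameters():
            np.testing.assert_array_equal(p.data, g_before[k])


class TestSparseProjection:
    def test_shapes_and_linearity(self):
        _, _, _, proj, rng = _small_setup()
        x = rng.standard_normal((3, 6, 64))
        Z = proj(x)
        assert Z.shape == (3, 4, 64)
        np.testing.assert_allclose(proj(2 * x), 2 * Z, rtol=1e-5)

    def test_self_adjointness(self):
        """<Fx, y> == <x, F*y> for the projection + band-filter operator."""
        _, _, _, proj, rng = _small_setup()
        x = rng.standard_normal((1, 6, 64))
        y = rng.standard_normal((1, 4, 64))
        lhs = float((proj(x) * y).sum())
        rhs = float((x * proj.backward(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-8)


class TestTrainingLoop:
    def test_history_and_checkpoints(self, tmp_path, rng):
        X = rng.standard_normal((10, 6, 64))
        config = GANTrainingConfig(batch_size=5, n_epochs=2, seed=4,
                                   checkpoint_every=1)
        gen, hist = train_fbgan(X, None, config,
                                gen_spec=GeneratorSpec.small(6, 64, noise_dim=8),
                                raw_spec=DiscriminatorSpec.small("raw", 6, 64),
                                fs=64.0, checkpoint_dir=tmp_path)
        assert len(hist) == 2
        assert (tmp_path / "fbgan_epoch0001.npz").exists()
        assert (tmp_path / "fbgan_final.npz").exists()
        reloaded = load_checkpoint(tmp_path / "fbgan_final.npz")
        z = rng.standard_normal((2, 8)).astype(np.float32)
        gen.eval(), reloaded.eval()
        np.testing.assert_array_equal(gen(z), reloaded(z))

    def test_same_seed_same_history(self, rng):
        X = np.random.default_rng(8).standard_normal((10, 6, 64))
        config = GANTrainingConfig(batch_size=5, n_epochs=2, seed=11)
        kw = dict(gen_spec=GeneratorSpec.small(6, 64, noise_dim=8),
                  raw_spec=DiscriminatorSpec.small("raw", 6, 64), fs=64.0)
        _, h1 = train_fbgan(X, None, config, **kw)
        _, h2 = train_fbgan(X, None, config, **kw)
        assert h1 == h2

    def test_too_few_trials_raises(self, rng):
        with pytest.raises(ValueError, match="batch_size"):
            train_fbgan(rng.standard_normal((3, 6, 64)), None,
                        GANTrainingConfig(batch_size=5),
                        gen_spec=GeneratorSpec.small(6, 64, noise_dim=8),
                        raw_spec=DiscriminatorSpec.small("raw", 6, 64), fs=64.0)

    def test_generated_psd_peaks_in_training_band(self):
        from mieeg.experiments import fbgan_psd_study
        real_peak, fake_peak = fbgan_psd_study(seed=1)
        assert 8.0 <= real_peak <= 12.0
        assert 8.0 <= fake_peak <= 12.0


class TestGenerate:
    def _gen(self):
        return build_generator(GeneratorSpec.small(6, 32, noise_dim=8), seed=0)

    def test_seeded_sampling_is_reproducible(self):
        gen = self._gen()
        a = generate(gen, 1, seed=42)
        b = generate(gen, 1, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shapes_and_provenance(self):
        out = generate(self._gen(), 7, seed=1, class_label=3, subject_id="S9")
        assert out.data.shape == (7, 6, 32)
        assert np.isfinite(out.data).all()
        assert (out.class_label, out.subject_id, out.seed) == (3, "S9", 1)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate(self._gen(), 0)
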