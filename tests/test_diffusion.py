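import numpy as np
import pytest

from acpdiff import SyntheticSpec, generate_peptide_dataset
from acpdiff.diffusion import (
    BFM,
    TFAM,
    Denoiser,
    DiffusionConfig,
    DiffusionGenerator,
    decode_to_sequences,
    descriptor_features,
    dpm_solver_sample,
    export_batches,
    make_schedule,
    q_sample,
    train_denoiser,
)
from acpdiff.nn import Tensor
from acpdiff.records import read_peptides


class TestSchedule:
    def test_alpha_bar_strictly_decreasing(self):
        s = make_schedule(500)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert 0 < s.alpha_bar[-1] < s.alpha_bar[0] < 1

    def test_beta_linear(self):
        s = make_schedule(100, 1e-4, 0.02)
        assert s.beta[0] == pytest.approx(1e-4)
        assert s.beta[-1] == pytest.approx(0.02)
        assert np.allclose(np.diff(s.beta), np.diff(s.beta)[0])

    def test_short_schedule_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(1)

    def test_q_sample_closed_form(self, rng):
        s = make_schedule(50)
        x0 = rng.standard_normal((3, 4))
        eps = rng.standard_normal((3, 4))
        t = np.array([0, 25, 49])
        out = q_sample(x0, t, eps, s)
        ab = s.alpha_bar[t][:, None]
        assert np.allclose(out, np.sqrt(ab) * x0 + np.sqrt(1 - ab) * eps)

    def test_q_sample_t_out_of_range(self, rng):
        s = make_schedule(10)
        with pytest.raises(ValueError):
            q_sample(np.zeros((1, 2)), 10, np.zeros((1, 2)), s)


class TestModules:
    def test_bfm_residual_shape(self, rng):
        bfm = BFM(4, (3, 7, 15), rng)
        x = Tensor(rng.standard_normal((2, 4, 20)))
        assert bfm(x).shape == (2, 4, 20)

    def test_tfam_conservation(self, rng):
        tfam = TFAM(4, (3, 5, 7), rng)
        t1 = Tensor(rng.standard_normal((3, 4, 12)))
        t2 = Tensor(rng.standard_normal((3, 4, 12)))
        b1, b2 = tfam.attention_weights(t1, t2)
        assert np.allclose(b1 + b2, 4.0, atol=1e-12)
        assert np.all(b1 > 1.0) and np.all(b2 > 1.0)

    def test_tfam_shape_mismatch_rejected(self, rng):
        tfam = TFAM(4, (3,), rng)
        with pytest.raises(ValueError):
            tfam(Tensor(np.zeros((1, 4, 8))), Tensor(np.zeros((1, 4, 9))))

    def test_denoiser_output_shape(self, rng):
        cfg = DiffusionConfig(input_dim=40, channels=4, train_steps=1)
        net = Denoiser(cfg, rng)
        out = net(rng.standard_normal((5, 40)), 0.5, np.array([0, 1, 2, 3, 4]))
        assert out.shape == (5, 40)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            DiffusionConfig(input_dim=41, channels=4)


class TestSampling:
    def test_oracle_point_mass_recovery(self):
        s = make_schedule(1000)
        x0 = np.array([[1.5, -2.0, 0.3]])

        def oracle(x, t_frac):
            t = min(max(int(round(t_frac * s.T)), 0), s.T - 1)
            ab = s.alpha_bar[t]
            return (x - np.sqrt(ab) * x0) / np.sqrt(1 - ab)

        z = np.random.default_rng(0).standard_normal((6, 3))
        out = dpm_solver_sample(z, oracle, s, steps=25)
        assert np.max(np.abs(out - x0)) < 1e-6

    def test_oracle_full_and_fast_paths_agree(self):
        s = make_schedule(1000)
        x0 = np.array([[0.7, -0.4]])

        def oracle(x, t_frac):
            t = min(max(int(round(t_frac * s.T)), 0), s.T - 1)
            ab = s.alpha_bar[t]
            return (x - np.sqrt(ab) * x0) / np.sqrt(1 - ab)

        z = np.random.default_rng(1).standard_normal((4, 2))
        fast = dpm_solver_sample(z, oracle, s, steps=25)
        full = dpm_solver_sample(z, oracle, s, steps=1000)
        assert np.allclose(fast, full, atol=1e-8)

    def test_steps_out_of_range(self):
        s = make_schedule(100)
        with pytest.raises(ValueError):
            dpm_solver_sample(np.zeros((1, 2)), lambda x, t: x, s, steps=0)

    def test_clip_bounds_output(self):
        s = make_schedule(1000)
        z = np.random.default_rng(2).standard_normal((3, 2)) * 10

        def wild(x, t_frac):
            return -x  # adversarial denoiser that amplifies

        out = dpm_solver_sample(z, wild, s, steps=10, clip_x0=3.0)
        assert np.all(np.abs(out) <= 3.0)


class TestTrainingAndRecovery:
    def test_gaussian_mean_recovery(self):
        rng = np.random.default_rng(1)
        mu = np.array([3.0, -2.0])
        data = rng.standard_normal((500, 2)) + mu
        cfg = DiffusionConfig(input_dim=2, channels=1, train_steps=1500, seed=7)
        gen = DiffusionGenerator.fit(features=data, config=cfg)
        latents = gen.sample_latents(500, None, seed=11)
        samples = latents * gen.scaler_scale + gen.scaler_mean
        assert np.all(np.abs(samples.mean(axis=0) - mu) < 0.15)

    def test_loss_decreases(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((200, 8))
        cfg = DiffusionConfig(input_dim=8, channels=2, train_steps=300, seed=3)
        _, history = train_denoiser(data, None, make_schedule(cfg.T), cfg)
        assert np.mean(history[-50:]) < np.mean(history[:50])

    def test_non_finite_features_rejected(self):
        cfg = DiffusionConfig(input_dim=4, channels=1, train_steps=1)
        with pytest.raises(ValueError):
            train_denoiser(np.array([[1.0, np.inf, 0, 0]]), None, make_schedule(10), cfg)


class TestDecoding:
    def test_length_bounds_and_determinism(self, rng):
        z0 = rng.standard_normal((30, 420))
        mean, scale = np.zeros(420), np.ones(420)
        batch1 = decode_to_sequences(z0, mean, scale, seed=5)
        batch2 = decode_to_sequences(z0, mean, scale, seed=5)
        assert all(8 <= len(r) <= 50 for r in batch1.records)
        assert [r.sequence for r in batch1.records] == [r.sequence for r in batch2.records]

    def test_label_annotated(self, rng):
        z0 = rng.standard_normal((3, 420))
        batch = decode_to_sequences(z0, np.zeros(420), np.ones(420), seed=1, label=4)
        assert all(r.label == 4 for r in batch.records)
        assert batch.records[0].id.startswith("gen4")

    def test_descriptor_features_shape(self, small_records):
        X = descriptor_features(small_records)
        assert X.shape == (len(small_records), 420)


@pytest.fixture(scope="module")
def peptide_generator():
    records = generate_peptide_dataset(
        SyntheticSpec(class_counts=(30,) * 9, separability=0.6, seed=3)
    )
    cfg = DiffusionConfig(train_steps=150, seed=5)
    return DiffusionGenerator.fit(records=records, config=cfg)


class TestGenerator:
    def test_generated_lengths_in_bounds(self, peptide_generator):
        batch = peptide_generator.generate(label=2, n=20, seed=9)
        assert len(batch.records) == 20
        assert all(8 <= len(r) <= 50 for r in batch.records)

    def test_unknown_label_rejected(self, peptide_generator):
        with pytest.raises(ValueError, match="unknown label"):
            peptide_generator.generate(label=9, n=2)

    def test_generation_deterministic(self, peptide_generator):
        a = peptide_generator.generate(label=0, n=5, seed=3)
        b = peptide_generator.generate(label=0, n=5, seed=3)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_save_load_round_trip(self, peptide_generator, tmp_path):
        path = tmp_path / "gen.npz"
        peptide_generator.save(path)
        back = DiffusionGenerator.load(path)
        a = peptide_generator.generate(label=1, n=4, seed=2)
        b = back.generate(label=1, n=4, seed=2)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_export_batches(self, peptide_generator, tmp_path):
        batches = [peptide_generator.generate(label=k, n=3, seed=k) for k in (0, 1)]
        export_batches(batches, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = read_peptides(tmp_path / "generated_label0.fasta")
        assert len(back) == 3
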