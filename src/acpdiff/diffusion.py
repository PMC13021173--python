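"""Conditional denoising-diffusion generation of peptide feature vectors.

The generator learns the distribution of the 420-dimensional invertible
descriptor subspace (amino-acid composition + dipeptide frequency,
standardized) under the standard forward process
``x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε`` with a linear β schedule, trains an
ε-prediction denoiser by MSE, and samples deterministically with a
first-order ODE solver on uniformly spaced log-SNR knots (a DPM-Solver-1
update), finishing with an exact denoise-to-data step.

The denoiser couples two fusion blocks:

* **BFM** — parallel 1-D convolutions at receptive fields {3, 7, 15} over
  the time-conditioned input, summed, plus a residual connection.
* **TFAM** — two-branch attention over the temporal states
  ``T1`` (time-conditioned input) and ``T2`` (BFM output): multi-scale
  Conv+ReLU sums at kernels {3, 5, 7}, channel weights from a branch-wise
  softmax over pooled descriptors, spatial weights from a branch-wise
  softmax of two identical 2-D convolutions, and residual fusion
  coefficients ``β_i = 1 + α_c(i) + α_s(i)``, so ``β₁+β₂ = 4`` always.

Sampled latents are decoded to 8–50-residue sequences through a
first-order Markov chain reconstructed from the recovered composition and
dipeptide blocks.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptors import physchem_vector
from .nn import Adam, Conv1d, Conv2d, Embedding, Linear, Module, Tensor, concat, sinusoidal_embedding
from .records import ALPHABET, N_CLASSES, PeptideRecord, write_peptides

LENGTH_BOUNDS = (8, 50)
DESCRIPTOR_SUBSPACE = 420  # composition (20) + dipeptide (400)


# ---------------------------------------------------------------------------
# Schedule and forward process
# ---------------------------------------------------------------------------

@dataclass
class DiffusionSchedule:
    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray


def make_schedule(T: int = 1000, beta_start: float = 1e-4, beta_end: float = 0.02) -> DiffusionSchedule:
    """Linear β schedule; ᾱ is the running product of (1−β), strictly decreasing."""
    if T < 2:
        raise ValueError("schedule needs T >= 2")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


def q_sample(x0: np.ndarray, t: np.ndarray | int, eps: np.ndarray,
             schedule: DiffusionSchedule) -> np.ndarray:
    """Forward noising draw x_t = √ᾱ_t·x0 + √(1−ᾱ_t)·ε."""
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t >= schedule.T):
        raise ValueError("t out of schedule range")
    ab = schedule.alpha_bar[t]
    ab = np.expand_dims(ab, axis=tuple(range(np.ndim(ab), np.ndim(x0))))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


# ---------------------------------------------------------------------------
# Denoiser network (BFM + TFAM)
# ---------------------------------------------------------------------------

@dataclass
class DiffusionConfig:
    input_dim: int = DESCRIPTOR_SUBSPACE
    channels: int = 4
    time_dim: int = 32
    n_labels: int = N_CLASSES
    bfm_kernels: tuple[int, ...] = (3, 7, 15)
    tfam_kernels: tuple[int, ...] = (3, 5, 7)
    T: int = 1000
    learning_rate: float = 2e-3
    train_steps: int = 600
    batch_size: int = 64
    sample_steps: int = 25
    clip_x0: float = 3.0  # dynamic-thresholding bound in standardized space
    seed: int = 42

    def __post_init__(self) -> None:
        if self.input_dim % self.channels:
            raise ValueError("input_dim must be divisible by channels")


class BFM(Module):
    """Bitemporal fusion: parallel multi-receptive-field 1-D convs + residual."""

    def __init__(self, channels: int, kernels: tuple[int, ...], rng: np.random.Generator):
        self.convs = [Conv1d(channels, channels, k, rng) for k in kernels]

    def __call__(self, x: Tensor) -> Tensor:
        out = x
        for conv in self.convs:
            out = out + conv(x)
        return out


class TFAM(Module):
    """Two-branch channel/spatial attention fusion with β₁+β₂ = 4 conservation."""

    def __init__(self, channels: int, kernels: tuple[int, ...], rng: np.random.Generator):
        self.scale_convs_1 = [Conv1d(channels, channels, k, rng) for k in kernels]
        self.scale_convs_2 = [Conv1d(channels, channels, k, rng) for k in kernels]
        self.channel_conv_1 = Conv1d(4, 1, 3, rng)
        self.channel_conv_2 = Conv1d(4, 1, 3, rng)
        self.spatial_conv_1 = Conv2d(4, 1, (1, 7), rng)
        self.spatial_conv_2 = Conv2d(4, 1, (1, 7), rng)

    @staticmethod
    def _multiscale(x: Tensor, convs) -> Tensor:
        out = None
        for conv in convs:
            term = conv(x).relu()
            out = term if out is None else out + term
        return out

    def __call__(self, t1: Tensor, t2: Tensor) -> Tensor:
        if t1.shape != t2.shape:
            raise ValueError("temporal states must share one shape")
        B, C, L = t1.shape
        h1 = self._multiscale(t1, self.scale_convs_1)
        h2 = self._multiscale(t2, self.scale_convs_2)

        # channel attention: pooled joint descriptor (B, 4, C) → branch softmax
        p_eps = concat(
            [
                h1.mean(axis=2, keepdims=True).transpose(0, 2, 1),
                h1.max(axis=2, keepdims=True).transpose(0, 2, 1),
                h2.mean(axis=2, keepdims=True).transpose(0, 2, 1),
                h2.max(axis=2, keepdims=True).transpose(0, 2, 1),
            ],
            axis=1,
        )
        a_c = concat([self.channel_conv_1(p_eps), self.channel_conv_2(p_eps)], axis=1)
        a_c = a_c.softmax(axis=1)  # (B, 2, C)

        # spatial attention: channel-pooled descriptor (B, 4, L) → branch softmax
        p_s = concat(
            [
                h1.mean(axis=1, keepdims=True),
                h1.max(axis=1, keepdims=True),
                h2.mean(axis=1, keepdims=True),
                h2.max(axis=1, keepdims=True),
            ],
            axis=1,
        ).reshape(B, 4, 1, L)
        a_s = concat([self.spatial_conv_1(p_s), self.spatial_conv_2(p_s)], axis=1)
        a_s = a_s.reshape(B, 2, L).softmax(axis=1)

        beta1 = 1.0 + a_c[:, 0, :].reshape(B, C, 1) + a_s[:, 0, :].reshape(B, 1, L)
        beta2 = 1.0 + a_c[:, 1, :].reshape(B, C, 1) + a_s[:, 1, :].reshape(B, 1, L)
        return beta1 * h1 + beta2 * h2

    def attention_weights(self, t1: Tensor, t2: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """(β₁, β₂) broadcast to the grid shape — exposed for the conservation check."""
        B, C, L = t1.shape
        h1 = self._multiscale(t1, self.scale_convs_1)
        h2 = self._multiscale(t2, self.scale_convs_2)
        p_eps = concat(
            [
                h1.mean(axis=2, keepdims=True).transpose(0, 2, 1),
                h1.max(axis=2, keepdims=True).transpose(0, 2, 1),
                h2.mean(axis=2, keepdims=True).transpose(0, 2, 1),
                h2.max(axis=2, keepdims=True).transpose(0, 2, 1),
            ],
            axis=1,
        )
        a_c = concat([self.channel_conv_1(p_eps), self.channel_conv_2(p_eps)], axis=1).softmax(axis=1)
        p_s = concat(
            [
                h1.mean(axis=1, keepdims=True),
                h1.max(axis=1, keepdims=True),
                h2.mean(axis=1, keepdims=True),
                h2.max(axis=1, keepdims=True),
            ],
            axis=1,
        ).reshape(B, 4, 1, L)
        a_s = concat([self.spatial_conv_1(p_s), self.spatial_conv_2(p_s)], axis=1)
        a_s = a_s.reshape(B, 2, L).softmax(axis=1)
        b1 = 1.0 + a_c.data[:, 0, :, None] + a_s.data[:, 0, None, :]
        b2 = 1.0 + a_c.data[:, 1, :, None] + a_s.data[:, 1, None, :]
        return b1, b2


class Denoiser(Module):
    """ε-prediction network over (B, input_dim) vectors.

    Time and label conditioning enter as a feature-wise affine modulation of
    the input map (zero-initialized scale/shift heads, so the untrained
    network starts at the unconditioned identity map); a learned scalar skip
    on the noisy input gives the network a direct linear route to the
    time-scaled component of ε.
    """

    def __init__(self, config: DiffusionConfig, rng: np.random.Generator):
        self.config = config
        C = config.channels
        self.time_scale = Linear(config.time_dim, C, rng, zero_init=True)
        self.time_shift = Linear(config.time_dim, C, rng, zero_init=True)
        self.label_embed = Embedding(config.n_labels + 1, C, rng)
        self.bfm = BFM(C, config.bfm_kernels, rng)
        self.tfam = TFAM(C, config.tfam_kernels, rng)
        self.out = Linear(config.input_dim, config.input_dim, rng)
        self.skip = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x: np.ndarray | Tensor, t: np.ndarray | float,
                 labels: np.ndarray | None = None) -> Tensor:
        cfg = self.config
        x = x if isinstance(x, Tensor) else Tensor(x)
        B = x.shape[0]
        C, L = cfg.channels, cfg.input_dim // cfg.channels
        t = np.broadcast_to(np.asarray(t, dtype=float), (B,))
        temb = Tensor(sinusoidal_embedding(t, cfg.time_dim))
        if labels is None:
            labels = np.full(B, cfg.n_labels)
        scale = (self.time_scale(temb) + self.label_embed(labels)).reshape(B, C, 1)
        shift = self.time_shift(temb).reshape(B, C, 1)
        t1 = x.reshape(B, C, L) * (1.0 + scale) + shift
        t2 = self.bfm(t1)
        fused = self.tfam(t1, t2)
        return self.out(fused.reshape(B, cfg.input_dim)) + x * self.skip[0]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_denoiser(features: np.ndarray, labels: np.ndarray | None,
                   schedule: DiffusionSchedule, config: DiffusionConfig,
                   rng: np.random.Generator | None = None) -> tuple[Denoiser, list[float]]:
    """ε-prediction MSE training with Adam; returns the network and loss history."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    rng = rng or np.random.default_rng(config.seed)
    network = Denoiser(config, rng)
    optimizer = Adam(network.parameters(), lr=config.learning_rate)
    n = len(features)
    history: list[float] = []
    for _ in range(config.train_steps):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        x0 = features[idx]
        batch_labels = labels[idx] if labels is not None else None
        t = rng.integers(0, schedule.T, size=len(idx))
        eps = rng.standard_normal(x0.shape)
        x_t = q_sample(x0, t, eps, schedule)
        pred = network(x_t, t / schedule.T, batch_labels)
        diff = pred - Tensor(eps)
        loss = (diff * diff).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite diffusion loss")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        history.append(float(loss.data))
    return network, history


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def dpm_solver_sample(z: np.ndarray, eps_fn, schedule: DiffusionSchedule,
                      steps: int = 25, clip_x0: float | None = None) -> np.ndarray:
    """Deterministic first-order ODE sampling on uniform log-SNR knots.

    ``eps_fn(x, t_frac)`` predicts ε at continuous time ``t_frac = t/T``.
    The final step denoises exactly to the data prediction
    ``x̂₀ = (x − σ·ε̂)/α``, so an oracle denoiser for a point mass returns
    that point to numerical precision.

    ``clip_x0`` optionally bounds the implied data prediction at every step
    (dynamic thresholding in the standardized training space); the ε̂ used by
    the update is recomputed from the clipped prediction.  With trained,
    imperfect denoisers this prevents trajectory blow-up; leave it ``None``
    for exact-oracle analyses.
    """
    if not 1 <= steps <= schedule.T:
        raise ValueError("steps out of range")
    ab = schedule.alpha_bar
    lam = 0.5 * np.log(ab / (1.0 - ab))  # log-SNR, increasing as t -> 0
    targets = np.linspace(lam[-1], lam[0], steps + 1)
    knots = [int(np.argmin(np.abs(lam - lt))) for lt in targets]
    knots[0], knots[-1] = schedule.T - 1, 0
    # deduplicate while preserving strictly decreasing t
    path = [knots[0]]
    for kn in knots[1:]:
        if kn < path[-1]:
            path.append(kn)
    if path[-1] != 0:
        path.append(0)

    x = np.asarray(z, dtype=float)
    for t_cur, t_next in zip(path[:-1], path[1:]):
        a_t, s_t = np.sqrt(ab[t_cur]), np.sqrt(1.0 - ab[t_cur])
        a_s, s_s = np.sqrt(ab[t_next]), np.sqrt(1.0 - ab[t_next])
        eps_hat = np.asarray(eps_fn(x, t_cur / schedule.T))
        if clip_x0 is not None:
            x0_pred = np.clip((x - s_t * eps_hat) / a_t, -clip_x0, clip_x0)
            eps_hat = (x - a_t * x0_pred) / s_t
        h = np.log(a_s / s_s) - np.log(a_t / s_t)
        x = (a_s / a_t) * x - s_s * np.expm1(h) * eps_hat
    # exact denoise-to-data at the last knot
    a0, s0 = np.sqrt(ab[path[-1]]), np.sqrt(1.0 - ab[path[-1]])
    eps_hat = np.asarray(eps_fn(x, path[-1] / schedule.T))
    x0 = (x - s0 * eps_hat) / a0
    return np.clip(x0, -clip_x0, clip_x0) if clip_x0 is not None else x0


# ---------------------------------------------------------------------------
# Decoding and the end-to-end generator
# ---------------------------------------------------------------------------

@dataclass
class GenerationBatch:
    label: int | None
    seed: int
    bounds: tuple[int, int]
    records: list[PeptideRecord]
    latent_ids: list[int]

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        assert all(lo <= len(r) <= hi for r in self.records)


def decode_to_sequences(z0: np.ndarray, scaler_mean: np.ndarray, scaler_scale: np.ndarray,
                        bounds: tuple[int, int] = LENGTH_BOUNDS, seed: int = 0,
                        label: int | None = None) -> GenerationBatch:
    """Decode standardized descriptor-space latents to peptide sequences.

    Per latent: un-standardize; rebuild a first-order Markov transition
    matrix from the dipeptide block (negatives clamped, additive smoothing
    1e-3, rows renormalized) and an initial-residue distribution from the
    composition block; draw the length uniformly from ``bounds``; sample the
    chain.  Deterministic given ``seed``.
    """
    z0 = np.atleast_2d(np.asarray(z0, dtype=float))
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    records: list[PeptideRecord] = []
    alphabet = list(ALPHABET)
    for i, latent in enumerate(z0):
        raw = latent * scaler_scale + scaler_mean
        comp = np.clip(raw[:20], 0.0, None)
        trans = np.clip(raw[20:420].reshape(20, 20), 0.0, None)
        if comp.sum() == 0 and trans.sum() == 0:
            warnings.warn("all-zero recovered blocks; falling back to uniform decoding")
        comp = comp + 1e-3
        comp = comp / comp.sum()
        trans = trans + 1e-3
        trans = trans / trans.sum(axis=1, keepdims=True)
        length = int(rng.integers(lo, hi + 1))
        state = rng.choice(20, p=comp)
        chars = [alphabet[state]]
        for _ in range(length - 1):
            state = rng.choice(20, p=trans[state])
            chars.append(alphabet[state])
        prefix = f"gen{label}" if label is not None else "gen"
        records.append(
            PeptideRecord(id=f"{prefix}_{i}", sequence="".join(chars), label=label,
                          source="diffusion-generated")
        )
    return GenerationBatch(label=label, seed=seed, bounds=bounds, records=records,
                           latent_ids=list(range(len(z0))))


def descriptor_features(records) -> np.ndarray:
    """(n, 420) composition+dipeptide matrix — the generator's training space."""
    return np.stack([physchem_vector(r.sequence).values[:DESCRIPTOR_SUBSPACE]
                     for r in records])


@dataclass
class DiffusionGenerator:
    """Trained generator: standardizer + denoiser + schedule."""

    config: DiffusionConfig
    schedule: DiffusionSchedule
    network: Denoiser
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    @classmethod
    def fit(cls, records=None, features: np.ndarray | None = None,
            labels: np.ndarray | None = None,
            config: DiffusionConfig | None = None) -> "DiffusionGenerator":
        config = config or DiffusionConfig()
        if features is None:
            if records is None:
                raise ValueError("provide records or features")
            features = descriptor_features(records)
            labels = np.array([r.label for r in records]) if records[0].label is not None else None
        features = np.asarray(features, dtype=float)
        mean = features.mean(axis=0)
        scale = features.std(axis=0)
        scale[scale == 0] = 1.0
        standardized = (features - mean) / scale
        schedule = make_schedule(config.T)
        network, history = train_denoiser(standardized, labels, schedule, config)
        return cls(config=config, schedule=schedule, network=network,
                   scaler_mean=mean, scaler_scale=scale, loss_history=history)

    def sample_latents(self, n: int, label: int | None, seed: int,
                       steps: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.input_dim))
        labels = None if label is None else np.full(n, label)

        def eps_fn(x, t_frac):
            return self.network(x, t_frac, labels).data

        return dpm_solver_sample(z, eps_fn, self.schedule,
                                 steps or self.config.sample_steps,
                                 clip_x0=self.config.clip_x0)

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Versioned single-file archive (npz): config, scaler, weights."""
        cfg = self.config
        payload = {
            "format_version": self.FORMAT_VERSION,
            "cfg_input_dim": cfg.input_dim,
            "cfg_channels": cfg.channels,
            "cfg_time_dim": cfg.time_dim,
            "cfg_n_labels": cfg.n_labels,
            "cfg_bfm_kernels": np.array(cfg.bfm_kernels),
            "cfg_tfam_kernels": np.array(cfg.tfam_kernels),
            "cfg_T": cfg.T,
            "cfg_sample_steps": cfg.sample_steps,
            "cfg_clip_x0": -1.0 if cfg.clip_x0 is None else cfg.clip_x0,
            "cfg_seed": cfg.seed,
            "scaler_mean": self.scaler_mean,
            "scaler_scale": self.scaler_scale,
        }
        for i, arr in enumerate(self.network.state_dict()):
            payload[f"param_{i}"] = arr
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "DiffusionGenerator":
        data = np.load(path)
        version = int(data["format_version"])
        if version != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported generator archive version {version}")
        clip = float(data["cfg_clip_x0"])
        config = DiffusionConfig(
            input_dim=int(data["cfg_input_dim"]),
            channels=int(data["cfg_channels"]),
            time_dim=int(data["cfg_time_dim"]),
            n_labels=int(data["cfg_n_labels"]),
            bfm_kernels=tuple(int(k) for k in data["cfg_bfm_kernels"]),
            tfam_kernels=tuple(int(k) for k in data["cfg_tfam_kernels"]),
            T=int(data["cfg_T"]),
            sample_steps=int(data["cfg_sample_steps"]),
            clip_x0=None if clip < 0 else clip,
            seed=int(data["cfg_seed"]),
        )
        network = Denoiser(config, np.random.default_rng(config.seed))
        n_params = len(network.parameters())
        network.load_state_dict([data[f"param_{i}"] for i in range(n_params)])
        return cls(config=config, schedule=make_schedule(config.T), network=network,
                   scaler_mean=data["scaler_mean"], scaler_scale=data["scaler_scale"])

    def generate(self, label: int | None, n: int, seed: int = 0,
                 bounds: tuple[int, int] = LENGTH_BOUNDS) -> GenerationBatch:
        if label is not None and not 0 <= label < self.config.n_labels:
            raise ValueError(f"unknown label {label}")
        z0 = self.sample_latents(n, label, seed)
        return decode_to_sequences(z0, self.scaler_mean, self.scaler_scale,
                                   bounds=bounds, seed=seed + 1, label=label)


def generate(label: int | None, n: int, model: DiffusionGenerator,
             seed: int = 0) -> GenerationBatch:
    return model.generate(label, n, seed=seed)


def export_batches(batches: list[GenerationBatch], out_dir: str | Path) -> None:
    """One FASTA per label plus a CSV manifest (id, label, length, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "length", "seed"])
        for batch in batches:
            name = f"generated_label{batch.label}.fasta" if batch.label is not None \
                else "generated.fasta"
            write_peptides(batch.records, out_dir / name, format="fasta")
            for rec in batch.records:
                writer.writerow([rec.id, batch.label, len(rec), batch.seed])
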