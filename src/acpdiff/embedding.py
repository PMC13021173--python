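"""Sequence embeddings, feature fusion and PCA reduction.

Each peptide is represented by a 1024-dimensional sequence embedding fused
with the 430-dimensional physicochemical block into a 1454-dimensional
vector, which is standardized and reduced to 200 principal components
before classification.

Two embedding backends share one contract (1024 finite numbers per
sequence):

* :class:`HashedKmerBackend` — overlapping 3-mer hashing into 4096 count
  buckets followed by a fixed-seed Gaussian random projection to 1024 and
  L2 normalization.  Fully deterministic, requires no model download, and
  is the default.
* :class:`ProtBertBackend` — mean-pooled last-hidden-state of the
  pretrained ProtBERT protein language model, if the ``transformers``
  package and weights are available locally.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .descriptors import DescriptorVector, physchem_vector
from .records import validate_sequence

EMBED_DIM = 1024
FUSED_DIM = 1454
N_BUCKETS = 4096
REDUCED_DIM = 200


class HashedKmerBackend:
    """Deterministic k-mer hash + random-projection embedding (k=3)."""

    name = "hashed-kmer"
    dimension = EMBED_DIM
    deterministic = True

    def __init__(self, seed: int = 0, k: int = 3):
        self.seed = seed
        self.k = k
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((N_BUCKETS, EMBED_DIM)) / np.sqrt(N_BUCKETS)

    def embed(self, seq: str) -> np.ndarray:
        seq = validate_sequence(seq)
        counts = np.zeros(N_BUCKETS)
        k = min(self.k, len(seq))
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            digest = hashlib.blake2b(kmer.encode(), digest_size=8).digest()
            counts[int.from_bytes(digest, "little") % N_BUCKETS] += 1.0
        vec = counts @ self._projection
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


class ProtBertBackend:
    """Mean-pooled ProtBERT embedding (optional; needs ``transformers``)."""

    name = "protbert"
    dimension = EMBED_DIM
    deterministic = True

    def __init__(self, model_name: str = "Rostlab/prot_bert"):
        try:
            from transformers import BertModel, BertTokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "ProtBERT backend requires the 'transformers' package and local "
                "model weights; use HashedKmerBackend for a deterministic, "
                "download-free embedding with the same 1024-dim contract."
            ) from exc
        import torch  # noqa: F401  # pragma: no cover
        self._tokenizer = BertTokenizer.from_pretrained(model_name, do_lower_case=False)
        self._model = BertModel.from_pretrained(model_name).eval()

    def embed(self, seq: str) -> np.ndarray:  # pragma: no cover - optional
        import torch

        seq = validate_sequence(seq)
        tokens = self._tokenizer(" ".join(seq), return_tensors="pt")
        with torch.no_grad():
            hidden = self._model(**tokens).last_hidden_state
        return hidden.mean(dim=1).squeeze(0).numpy().astype(float)


def embed_sequence(seq: str, backend=None) -> np.ndarray:
    backend = backend or HashedKmerBackend()
    vec = np.asarray(backend.embed(seq), dtype=float)
    if vec.shape != (EMBED_DIM,) or not np.all(np.isfinite(vec)):
        raise ValueError(f"backend {backend.name!r} violated the embedding contract")
    return vec


@dataclass
class FusedFeature:
    values: np.ndarray
    stage: str = "raw"  # raw | standardized | reduced

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage in ("raw", "standardized"):
            if self.values.shape != (FUSED_DIM,):
                raise ValueError(
                    f"stage {self.stage!r} expects {FUSED_DIM} values, got {self.values.shape}"
                )
        elif self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("reduced feature must be a non-empty vector")


def fuse_features(embedding: np.ndarray, descriptors: DescriptorVector) -> FusedFeature:
    """Concatenate [embedding (1024) | descriptors (430)] → 1454 raw features."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape != (EMBED_DIM,):
        raise ValueError(f"embedding must have {EMBED_DIM} entries")
    return FusedFeature(np.concatenate([embedding, descriptors.values]))


def featurize(records, backend=None) -> np.ndarray:
    """Fused raw feature matrix (n × 1454) for a list of peptide records."""
    backend = backend or HashedKmerBackend()
    return np.stack(
        [
            fuse_features(embed_sequence(r.sequence, backend), physchem_vector(r.sequence)).values
            for r in records
        ]
    )


class ReductionModel:
    """Per-column standardizer followed by exact-SVD PCA.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making fitted models reproducible across runs.
    Fit on the training partition only.
    """

    FORMAT_VERSION = 1

    def __init__(self, n_components: int = REDUCED_DIM):
        self.n_components = n_components
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.components_: np.ndarray | None = None  # (n_features, n_components)
        self.explained_variance_ratio_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ReductionModel":
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= self.n_components:
            raise ValueError(
                f"need more than {self.n_components} samples to fit, got {X.shape[0]}"
            )
        scaler = StandardScaler()
        Z = scaler.fit_transform(X)
        self.mean_ = scaler.mean_
        # zero-variance columns get unit scale
        self.scale_ = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(Z)
        comps = pca.components_  # (n_components, n_features)
        signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        self.components_ = (comps * signs[:, None]).T
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("ReductionModel is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) / self.scale_ @ self.components_

    def save(self, path) -> None:
        np.savez(
            path,
            format_version=self.FORMAT_VERSION,
            mean=self.mean_,
            scale=self.scale_,
            components=self.components_,
            evr=self.explained_variance_ratio_,
        )

    @classmethod
    def load(cls, path) -> "ReductionModel":
        data = np.load(path)
        model = cls(n_components=data["components"].shape[1])
        model.mean_ = data["mean"]
        model.scale_ = data["scale"]
        model.components_ = data["components"]
        model.explained_variance_ratio_ = data["evr"]
        return model


def fit_reduction(X: np.ndarray, n_components: int = REDUCED_DIM) -> ReductionModel:
    return ReductionModel(n_components).fit(X)


def apply_reduction(model: ReductionModel, x: FusedFeature | np.ndarray) -> FusedFeature:
    if isinstance(x, FusedFeature):
        if x.stage == "reduced":
            raise ValueError("feature is already reduced")
        values = x.values
    else:
        values = np.asarray(x, dtype=float)
    reduced = model.transform(values[None, :])[0]
    return FusedFeature(reduced, stage="reduced")
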