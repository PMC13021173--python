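"""Synthetic, class-structured peptide datasets and feature-space mixtures.

These generators emulate the study conditions every pipeline stage is
exercised under: nine cancer-type classes with imbalanced counts
(majority:minority ≈ 4:1), sequence lengths 8–50 over the canonical
alphabet, and class-dependent residue-composition biases that make the
classes learnably separable.  They imitate compositional structure only —
not the motif grammar, positional correlations or evolutionary signal of
real anticancer peptides — so green tests certify the machinery, not
biological performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ALPHABET, N_CLASSES, PeptideRecord

#: Reference per-class sample counts scaled by 1/2 (imbalance profile preserved,
#: majority:minority ratio 368:105 ≈ 3.5:1 before scaling).
DEFAULT_CLASS_COUNTS = (55, 184, 116, 114, 53, 56, 144, 64, 86)

LENGTH_RANGE = (8, 50)


def _default_biases(n_classes: int, separability: float) -> np.ndarray:
    """Class residue-frequency distributions: each class concentrates mass on
    a distinct residue pair, mixed with the uniform background by
    ``separability`` in [0, 1] (0 → uniform, 1 → fully concentrated)."""
    uniform = np.full(20, 1.0 / 20.0)
    biases = np.empty((n_classes, 20))
    for c in range(n_classes):
        peak = np.zeros(20)
        peak[(2 * c) % 20] = 0.6
        peak[(2 * c + 1) % 20] = 0.4
        biases[c] = separability * peak + (1.0 - separability) * uniform
    return biases


@dataclass
class SyntheticSpec:
    n_classes: int = N_CLASSES
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    length_range: tuple[int, int] = LENGTH_RANGE
    separability: float = 0.6
    biases: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_counts) != self.n_classes:
            raise ValueError("class_counts length must equal n_classes")
        if any(c < 2 for c in self.class_counts):
            raise ValueError("every class needs at least 2 samples")
        if self.biases is None:
            self.biases = _default_biases(self.n_classes, self.separability)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.biases.shape != (self.n_classes, 20):
            raise ValueError("biases must be (n_classes, 20)")
        if np.any(self.biases < 0) or not np.allclose(self.biases.sum(axis=1), 1.0):
            raise ValueError("each bias vector must be a probability distribution")


def generate_peptide_dataset(spec: SyntheticSpec | None = None) -> list[PeptideRecord]:
    """Draw class-biased i.i.d. sequences; deterministic given ``spec.seed``."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(ALPHABET))
    lo, hi = spec.length_range
    records: list[PeptideRecord] = []
    for label, count in enumerate(spec.class_counts):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=spec.biases[label]))
            records.append(
                PeptideRecord(id=f"syn{label}_{i}", sequence=seq, label=label,
                              source="synthetic")
            )
    return records


def generate_feature_mixture(
    means: np.ndarray,
    covariances: np.ndarray,
    counts: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled Gaussian-mixture sample for feature-space tests.

    ``means`` is (k, d); ``covariances`` is (k, d, d); ``counts`` is (k,).
    Returns (X, y); deterministic given ``seed``.
    """
    means = np.asarray(means, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    counts = np.asarray(counts, dtype=int)
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for comp, (mu, cov, n) in enumerate(zip(means, covariances, counts)):
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals <= 0):
            raise ValueError(f"covariance of component {comp} is not positive definite")
        xs.append(rng.multivariate_normal(mu, cov, size=n, method="cholesky"))
        ys.append(np.full(n, comp))
    return np.concatenate(xs), np.concatenate(ys)
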