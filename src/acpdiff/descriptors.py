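"""Physicochemical descriptors for peptides.

The descriptor block used by the classifier is a 430-number vector laid out
as ``[amino-acid composition (20) | dipeptide frequency (400) | global
properties (10)]``.  The global segment carries length, molecular weight,
net charge at pH 7, isoelectric point, mean hydrophobicity, hydrophobic
moment, instability index, aromaticity, basic-residue fraction, and the
count of aromatic–basic residue pairs in close sequence proximity — the
quantities screened on generated candidates.

Net charge follows the Henderson–Hasselbalch formulation: each basic group
(N-terminus, H, K, R) contributes ``1/(1+10^(pH−pKa))`` and each acidic
group (C-terminus, D, E, C, Y) contributes ``−1/(1+10^(pKa−pH))``.  The
isoelectric point is the unique root of this monotone function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV

from .records import ALPHABET, validate_sequence

N_DESCRIPTORS = 430
_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Eisenberg consensus hydrophobicity scale (dimensionless, helix-wheel standard).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

_BASIC = set("HKR")
_ACIDIC_SIDE = set("DECY")
_AROMATIC = set("FWY")
_BASIC_KR = set("KR")


@dataclass(frozen=True)
class PKaSet:
    """Ionization constants (pH units) behind the charge and pI operations.

    The defaults reproduce the reference charge profile of short anticancer
    peptides at pH 7 to two decimals.
    """

    n_terminus: float = 8.0
    c_terminus: float = 3.1
    D: float = 3.65
    E: float = 4.25
    C: float = 8.3
    Y: float = 10.07
    H: float = 6.0
    K: float = 10.5
    R: float = 12.5

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")

    def basic(self) -> dict[str, float]:
        return {"H": self.H, "K": self.K, "R": self.R}

    def acidic(self) -> dict[str, float]:
        return {"D": self.D, "E": self.E, "C": self.C, "Y": self.Y}


DEFAULT_PKA = PKaSet()


@dataclass
class GlobalProperties:
    length: int
    molecular_weight: float
    net_charge: float
    isoelectric_point: float
    gravy: float
    hydrophobic_moment: float
    instability_index: float
    aromaticity: float

    def __post_init__(self) -> None:
        assert self.length >= 1
        assert 0.0 <= self.aromaticity <= 1.0
        assert self.hydrophobic_moment >= -1e-12


@dataclass
class DescriptorVector:
    """The 430-number physicochemical block with a named segment layout."""

    values: np.ndarray
    layout: dict = field(
        default_factory=lambda: {"aac": 20, "dipeptide": 400, "global": 10}
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DESCRIPTORS,):
            raise ValueError(f"descriptor vector must have {N_DESCRIPTORS} entries")

    @property
    def aac(self) -> np.ndarray:
        return self.values[:20]

    @property
    def dipeptide(self) -> np.ndarray:
        return self.values[20:420]

    @property
    def global_block(self) -> np.ndarray:
        return self.values[420:]


def amino_acid_composition(seq: str) -> np.ndarray:
    """Fraction of each residue, ordered ACDEFGHIKLMNPQRSTVWY; sums to 1."""
    seq = validate_sequence(seq)
    out = np.zeros(20)
    for ch in seq:
        out[_INDEX[ch]] += 1.0
    return out / len(seq)


def dipeptide_frequency(seq: str) -> np.ndarray:
    """Adjacent-pair frequencies, row-major over the alphabet (400 entries).

    A length-1 sequence has no adjacent pairs and maps to the zero vector.
    """
    seq = validate_sequence(seq)
    out = np.zeros(400)
    if len(seq) == 1:
        return out
    for a, b in zip(seq, seq[1:]):
        out[_INDEX[a] * 20 + _INDEX[b]] += 1.0
    return out / (len(seq) - 1)


def net_charge(seq: str, pH: float = 7.0, pka: PKaSet = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at the given pH."""
    seq = validate_sequence(seq)
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    basic = pka.basic()
    acidic = pka.acidic()
    positive = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    negative = 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for ch in seq:
        if ch in basic:
            positive += 1.0 / (1.0 + 10.0 ** (pH - basic[ch]))
        elif ch in acidic:
            negative += 1.0 / (1.0 + 10.0 ** (acidic[ch] - pH))
    return positive - negative


def isoelectric_point(
    seq: str, pka: PKaSet = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly non-increasing in pH and the termini guarantee a
    sign change, so the root is unique.
    """
    seq = validate_sequence(seq)
    lo, hi = 1e-9, 14.0 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(
    seq: str, scale: dict[str, float] | None = None, angle: float = 100.0
) -> float:
    """Mean vector-sum hydrophobic moment μH at the given turn angle.

    μH = ‖Σ_k h_k (cos kδ, sin kδ)‖ / L with δ the angle in radians — the
    standard amphipathicity measure at 100° per residue for an α-helix.
    """
    seq = validate_sequence(seq)
    scale = EISENBERG if scale is None else scale
    try:
        h = np.array([scale[ch] for ch in seq])
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} missing from hydrophobicity scale")
    delta = np.deg2rad(angle)
    k = np.arange(len(seq))
    return float(np.hypot(np.sum(h * np.cos(k * delta)), np.sum(h * np.sin(k * delta))) / len(seq))


def instability_index(seq: str) -> float:
    """Guruprasad dipeptide-weight instability statistic (10/L)·Σ DIWV.

    Dipeptides absent from the published weight table count 1.0; a length-1
    sequence scores 0 by convention.
    """
    seq = validate_sequence(seq)
    if len(seq) == 1:
        return 0.0
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        total += _DIWV.get(a, {}).get(b, 1.0)
    return 10.0 * total / len(seq)


def aromatic_basic_pairs(seq: str, window: int = 3) -> int:
    """Count aromatic (W/F/Y) – basic (K/R) residue pairs within ``window`` positions."""
    seq = validate_sequence(seq)
    count = 0
    for i, a in enumerate(seq):
        for j in range(i + 1, min(i + window + 1, len(seq))):
            b = seq[j]
            if (a in _AROMATIC and b in _BASIC_KR) or (a in _BASIC_KR and b in _AROMATIC):
                count += 1
    return count


def global_properties(
    seq: str,
    pka: PKaSet = DEFAULT_PKA,
    scale: dict[str, float] | None = None,
) -> GlobalProperties:
    """Whole-sequence physicochemical profile used in candidate screening."""
    seq = validate_sequence(seq)
    scale = EISENBERG if scale is None else scale
    return GlobalProperties(
        length=len(seq),
        molecular_weight=_bio_molecular_weight(seq, seq_type="protein", monoisotopic=True),
        net_charge=net_charge(seq, 7.0, pka),
        isoelectric_point=isoelectric_point(seq, pka),
        gravy=float(np.mean([scale[ch] for ch in seq])),
        hydrophobic_moment=hydrophobic_moment(seq, scale),
        instability_index=instability_index(seq),
        aromaticity=sum(ch in _AROMATIC for ch in seq) / len(seq),
    )


def physchem_vector(
    seq: str, pka: PKaSet = DEFAULT_PKA, scale: dict[str, float] | None = None
) -> DescriptorVector:
    """The full 430-dim descriptor block: [aac(20) | dipeptide(400) | global(10)]."""
    seq = validate_sequence(seq)
    props = global_properties(seq, pka, scale)
    basic_fraction = sum(ch in _BASIC_KR for ch in seq) / len(seq)
    global_block = np.array(
        [
            props.length,
            props.molecular_weight,
            props.net_charge,
            props.isoelectric_point,
            props.gravy,
            props.hydrophobic_moment,
            props.instability_index,
            props.aromaticity,
            basic_fraction,
            aromatic_basic_pairs(seq),
        ],
        dtype=float,
    )
    values = np.concatenate(
        [amino_acid_composition(seq), dipeptide_frequency(seq), global_block]
    )
    return DescriptorVector(values)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero — the convention used in reported charge tables."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
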