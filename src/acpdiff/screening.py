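"""Post-generation screening: local alignment novelty, motifs, helical wheels.

Smith–Waterman local alignment with affine gaps (Gotoh recurrences) scores
each generated candidate against a reference panel; candidates whose
full-length identity to any reference reaches 90% are flagged as
near-duplicates.  Motif summaries count basic (K/R) and aromatic (W/F/Y)
residues and grade aromatic–basic proximity, the composition signature of
membrane-active anticancer peptides; helical-wheel coordinates place
residues at 100° increments for amphipathicity inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .descriptors import EISENBERG, hydrophobic_moment
from .records import validate_sequence

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass
class AlignmentResult:
    score: float
    a_start: int  # 1-based inclusive coordinates on each sequence
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str
    identity_pct: float   # over alignment columns, gaps included in denominator
    positive_pct: float
    gap_pct: float


_EMPTY = AlignmentResult(0.0, 0, 0, 0, 0, "", "", 0.0, 0.0, 0.0)


def smith_waterman(a: str, b: str, matrix=None, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal local alignment under affine gaps (Gotoh).

    A gap of length g costs ``gap_open + g·gap_extend``.  Traceback reports
    one optimal alignment with deterministic tie-breaking: diagonal beats a
    gap in ``b`` (up) beats a gap in ``a`` (left).
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    if not a or not b:
        return _EMPTY
    a = validate_sequence(a)
    b = validate_sequence(b)
    matrix = blosum62() if matrix is None else matrix
    n, m = len(a), len(b)
    NEG = -1e18
    # H: best local score; E: gap in a (left move); F: gap in b (up move)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, F[i][j], E[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best == 0.0:
        return _EMPTY

    # traceback with tie order diagonal > up (F) > left (E)
    i, j = best_pos
    state = "H"
    al_a: list[str] = []
    al_b: list[str] = []
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            sub = matrix[a[i - 1], b[j - 1]]
            if H[i][j] == H[i - 1][j - 1] + sub:
                al_a.append(a[i - 1])
                al_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b, consume a
            al_a.append(a[i - 1])
            al_b.append("-")
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "H"
            i -= 1
        else:  # state == "E": gap in a, consume b
            al_a.append("-")
            al_b.append(b[j - 1])
            if E[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
    al_a.reverse()
    al_b.reverse()
    cols = len(al_a)
    ident = sum(x == y for x, y in zip(al_a, al_b))
    positive = sum(
        x != "-" and y != "-" and matrix[x, y] > 0 for x, y in zip(al_a, al_b)
    )
    gaps = sum(x == "-" or y == "-" for x, y in zip(al_a, al_b))
    return AlignmentResult(
        score=float(best),
        a_start=i + 1, a_end=best_pos[0],
        b_start=j + 1, b_end=best_pos[1],
        aligned_a="".join(al_a), aligned_b="".join(al_b),
        identity_pct=100.0 * ident / cols,
        positive_pct=100.0 * positive / cols,
        gap_pct=100.0 * gaps / cols,
    )


@dataclass
class NoveltyHit:
    candidate_id: str
    best_reference_id: str
    score: float
    identity_pct: float
    positive_pct: float
    gap_pct: float
    full_length_identity_pct: float
    near_duplicate: bool


def _full_length_identity(a: str, b: str) -> float:
    """Identity of the best gapless end-to-end correspondence: matched
    positions over the longer length (100% iff the sequences are equal)."""
    if a == b:
        return 100.0
    longer, shorter = (a, b) if len(a) >= len(b) else (b, a)
    best = 0
    for offset in range(len(longer) - len(shorter) + 1):
        best = max(best, sum(x == y for x, y in
                             zip(shorter, longer[offset:offset + len(shorter)])))
    return 100.0 * best / len(longer)


def novelty_scan(candidates, references, matrix=None, gap_open: float = 11.0,
                 gap_extend: float = 1.0) -> list[NoveltyHit]:
    """Best-reference local-alignment hit per candidate.

    Candidates with full-length identity ≥ 90% to any reference are flagged
    as near-duplicates (boundary inclusive).
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    hits = []
    for cand in candidates:
        best_aln, best_ref = None, None
        max_full = 0.0
        for ref in references:
            aln = smith_waterman(cand.sequence, ref.sequence, matrix, gap_open, gap_extend)
            if best_aln is None or aln.score > best_aln.score:
                best_aln, best_ref = aln, ref
            max_full = max(max_full, _full_length_identity(cand.sequence, ref.sequence))
        hits.append(NoveltyHit(
            candidate_id=cand.id,
            best_reference_id=best_ref.id,
            score=best_aln.score,
            identity_pct=best_aln.identity_pct,
            positive_pct=best_aln.positive_pct,
            gap_pct=best_aln.gap_pct,
            full_length_identity_pct=max_full,
            near_duplicate=max_full >= 90.0,
        ))
    return hits


@dataclass
class MotifSummary:
    basic_count: int
    basic_breakdown: dict[str, int]
    aromatic_count: int
    aromatic_breakdown: dict[str, int]
    aromatic_basic_proximity: str  # absent | present | strong
    amphipathic_moment: float


def motif_summary(seq: str, proximity_window: int = 3,
                  helix_window: int = 11) -> MotifSummary:
    """Basic/aromatic residue counts and proximity grade.

    Proximity is *strong* with ≥2 aromatic–basic pairs within the window,
    *present* with ≥1, else *absent*.  The amphipathic moment is the maximum
    μH over all ``helix_window``-residue windows (whole sequence if shorter).
    """
    seq = validate_sequence(seq)
    basic = {r: seq.count(r) for r in "KR" if seq.count(r)}
    aromatic = {r: seq.count(r) for r in "WFY" if seq.count(r)}
    pairs = 0
    for i, x in enumerate(seq):
        for j in range(i + 1, min(i + proximity_window + 1, len(seq))):
            y = seq[j]
            if (x in "WFY" and y in "KR") or (x in "KR" and y in "WFY"):
                pairs += 1
    proximity = "strong" if pairs >= 2 else ("present" if pairs >= 1 else "absent")
    if len(seq) <= helix_window:
        moment = hydrophobic_moment(seq)
    else:
        moment = max(hydrophobic_moment(seq[i:i + helix_window])
                     for i in range(len(seq) - helix_window + 1))
    return MotifSummary(
        basic_count=sum(basic.values()),
        basic_breakdown=basic,
        aromatic_count=sum(aromatic.values()),
        aromatic_breakdown=aromatic,
        aromatic_basic_proximity=proximity,
        amphipathic_moment=moment,
    )


_HYDROPHOBIC = set("AILMFVWC")
_BASIC_SET = set("KRH")
_ACIDIC_SET = set("DE")


def helical_wheel(seq: str, angle: float = 100.0) -> list[dict]:
    """Per-residue helical-wheel coordinates: residue k sits at (angle·k) mod
    360 degrees, annotated with residue class and hydrophobicity."""
    seq = validate_sequence(seq)
    rows = []
    for k, ch in enumerate(seq):
        if ch in _HYDROPHOBIC:
            cls = "hydrophobic"
        elif ch in _BASIC_SET:
            cls = "basic"
        elif ch in _ACIDIC_SET:
            cls = "acidic"
        else:
            cls = "polar"
        rows.append({
            "position": k,
            "residue": ch,
            "angle_deg": (angle * k) % 360.0,
            "hydrophobicity": EISENBERG[ch],
            "residue_class": cls,
        })
    return rows
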