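"""Physicochemical profiling and motif screening of known peptides.

Walks through the descriptor layer on a handful of well-known membrane-
active peptides: net charge and isoelectric point from the Henderson-
Hasselbalch model, hydrophobic moment at the helical turn angle, the full
430-dim descriptor vector, and the motif/helical-wheel screening used on
generated candidates.

Run: python examples/01_descriptors_and_screening.py
"""

from acpdiff import (
    global_properties,
    helical_wheel,
    motif_summary,
    net_charge,
    physchem_vector,
    smith_waterman,
)
from acpdiff.descriptors import isoelectric_point, round_half_away

PEPTIDES = {
    "magainin-2": "GIGKFLHSAKKFGKAFVGEIMNS",
    "cecropin-P1-fragment": "KWKLFKKIEKVGQNIRDGIIKAGPAVAVVGQATQIAK",
    "aurein-1.2": "GLFDIIKKIAESF",
}

print("=== charge and pI ===")
for name, seq in PEPTIDES.items():
    q = round_half_away(net_charge(seq), 2)
    pI = isoelectric_point(seq)
    print(f"{name:<22} charge@pH7 {q:+.2f}   pI {pI:5.2f}")

print("\n=== global physicochemical profile (magainin-2) ===")
props = global_properties(PEPTIDES["magainin-2"])
for field in ("length", "molecular_weight", "net_charge", "isoelectric_point",
              "gravy", "hydrophobic_moment", "instability_index", "aromaticity"):
    print(f"{field:<20} {getattr(props, field):.3f}")

vec = physchem_vector(PEPTIDES["magainin-2"])
print(f"\ndescriptor vector: {vec.values.shape[0]} numbers "
      f"(aac {vec.aac.shape[0]} | dipeptide {vec.dipeptide.shape[0]} | "
      f"global {vec.global_block.shape[0]})")

print("\n=== motif summary ===")
for name, seq in PEPTIDES.items():
    m = motif_summary(seq)
    print(f"{name:<22} basic {m.basic_count} {m.basic_breakdown}  "
          f"aromatic {m.aromatic_count} {m.aromatic_breakdown}  "
          f"proximity {m.aromatic_basic_proximity}  muH {m.amphipathic_moment:.3f}")

print("\n=== helical wheel (first turn of magainin-2) ===")
for row in helical_wheel(PEPTIDES["magainin-2"])[:7]:
    print(f"pos {row['position']:>2}  {row['residue']}  "
          f"{row['angle_deg']:>5.1f} deg  {row['residue_class']}")

print("\n=== local alignment between two of them ===")
res = smith_waterman(PEPTIDES["magainin-2"], PEPTIDES["cecropin-P1-fragment"])
print(f"score {res.score:.1f}  identity {res.identity_pct:.1f}%  "
      f"gaps {res.gap_pct:.1f}%")
print(res.aligned_a)
print(res.aligned_b)
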