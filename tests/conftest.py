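import numpy as np
import pytest

from acpdiff import PeptideRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_records():
    """A tiny labeled record set spanning several classes."""
    seqs = [
        ("p0", "ITFIQFRMIH", 0),
        ("p1", "LQENDRAT", 1),
        ("p2", "PTARVIVWVYRCI", 2),
        ("p3", "KFSMDFFSCEWIPSTCRANNS", 3),
        ("p4", "YVSPAEASLVG", 4),
        ("p5", "GLWSKIKEVGKEAAKAAAKAAGKAALGAVSEAV", 5),
        ("p6", "KWKLFKKIEKVGQNIRDGIIKAGPAVAVVGQATQIAK", 6),
        ("p7", "FLPIIAKLLSGLL", 7),
        ("p8", "GIGKFLHSAKKFGKAFVGEIMNS", 8),
    ]
    return [PeptideRecord(id=i, sequence=s, label=lb) for i, s, lb in seqs]
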