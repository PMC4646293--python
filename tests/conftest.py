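import pytest

from micelledepth import AtomRef

# Reference benchmark: eleven protons with published solvent-PRE slopes
# (s^-1 mM^-1) and the center distances (Å) they imply at micelle radius
# 30 Å with g = 7.98 Å, k = 253 s^-1 mM^-1 Å^3.
TABLE1_ROWS = [
    (AtomRef(21, "TRP", "H"), 0.2338, 27.7),
    (AtomRef(22, "LEU", "HA"), 0.0972, 24.2),
    (AtomRef(23, "THR", "H"), 0.1252, 25.3),
    (AtomRef(23, "THR", "HA"), 0.1417, 25.8),
    (AtomRef(24, "GLY", "H"), 0.2258, 27.6),
    (AtomRef(25, "TRP", "H"), 0.0911, 23.9),
    (AtomRef(25, "TRP", "HE1"), 0.1168, 25.0),
    (AtomRef(26, "LEU", "H"), 0.0737, 22.9),
    (AtomRef(26, "LEU", "HB2"), 0.0640, 22.2),
    (AtomRef(28, "THR", "H"), 0.1530, 26.2),
    (AtomRef(29, "TRP", "H"), 0.1224, 25.2),
]


@pytest.fixture
def table1_rows():
    return TABLE1_ROWS
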