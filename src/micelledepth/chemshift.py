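"""Secondary chemical-shift analysis.

Observed 13Ca, 13CO and 1Ha shifts are compared with random-coil reference
values; systematic signed deviations indicate secondary structure.  Fully
formed helices shift Ca and CO downfield (positive deviation) and Ha upfield
(negative) by about +2.6, +1.7 and -0.38 ppm on average; sheets shift the
other way (about -1.4, -1.4, +0.38 ppm).  Because those magnitudes describe
fully formed elements, per-residue classification uses a configurable
fraction of them (``call_fraction``) after light smoothing along the
sequence, which suits partially formed or fraying elements in peptides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .types import ShiftRecord

__all__ = [
    "RandomCoilTable",
    "SecondaryShiftProfile",
    "ResidueShifts",
    "CsdThresholds",
    "StructureLabel",
    "builtin_random_coil_table",
    "secondary_shifts",
    "classify_residues",
]

#: Random-coil chemical shifts (ppm, DSS-referenced) for the 20 standard
#: residues: (Ca, CO, Ha).  Wishart-style aqueous random-coil values.
_RANDOM_COIL: dict[str, tuple[float, float, float]] = {
    "ALA": (52.5, 177.8, 4.35),
    "ARG": (56.0, 176.3, 4.38),
    "ASN": (52.8, 175.2, 4.75),
    "ASP": (54.2, 176.3, 4.76),
    "CYS": (58.2, 174.6, 4.65),
    "GLN": (55.7, 176.0, 4.37),
    "GLU": (56.6, 176.6, 4.29),
    "GLY": (45.1, 174.9, 3.97),
    "HIS": (55.0, 174.1, 4.63),
    "ILE": (61.1, 176.4, 4.17),
    "LEU": (55.1, 177.6, 4.17),
    "LYS": (56.2, 176.6, 4.36),
    "MET": (55.4, 176.3, 4.52),
    "PHE": (57.7, 175.8, 4.66),
    "PRO": (63.3, 177.3, 4.44),
    "SER": (58.3, 174.6, 4.50),
    "THR": (61.8, 174.7, 4.35),
    "TRP": (57.5, 176.1, 4.70),
    "TYR": (57.9, 175.9, 4.60),
    "VAL": (62.2, 176.3, 4.12),
}

_NUCLEI = ("CA", "CO", "HA")
# Observed atom labels mapped onto the three reference nuclei; carbonyl
# carbon is usually assigned as "C" in shift tables.
_ATOM_TO_NUCLEUS = {"CA": "CA", "C": "CO", "CO": "CO", "HA": "HA"}


@dataclass(frozen=True)
class RandomCoilTable:
    """Map (residue_name, nucleus) -> random-coil shift in ppm."""

    shifts: Mapping[tuple[str, str], float]
    provenance_label: str

    def get(self, residue_name: str, nucleus: str) -> Optional[float]:
        return self.shifts.get((residue_name.upper(), nucleus.upper()))


def builtin_random_coil_table() -> RandomCoilTable:
    """The packaged Wishart-style random-coil reference (Ca, CO, Ha)."""
    table = {
        (res, nuc): val
        for res, vals in _RANDOM_COIL.items()
        for nuc, val in zip(_NUCLEI, vals)
    }
    return RandomCoilTable(shifts=table, provenance_label="wishart-style-builtin")


def read_random_coil_table(path) -> RandomCoilTable:
    """Load a user random-coil table (TSV: resname, atom, shift_ppm)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    table = {
        (str(r.resname).upper(), _ATOM_TO_NUCLEUS.get(str(r.atom).upper(), str(r.atom).upper())):
            float(r.shift_ppm)
        for r in df.itertuples()
    }
    return RandomCoilTable(shifts=table, provenance_label=str(path))


class StructureLabel(str, Enum):
    HELIX = "helix"
    SHEET = "sheet"
    COIL = "coil"
    INSUFFICIENT = "insufficient"


@dataclass
class ResidueShifts:
    """Secondary-shift deviations of one residue (any subset present)."""

    residue_number: int
    residue_name: str
    delta: dict[str, float] = field(default_factory=dict)  # nucleus -> ppm
    label: StructureLabel = StructureLabel.INSUFFICIENT


@dataclass
class SecondaryShiftProfile:
    """Per-residue deviation profile; ``gaps`` lists residues absent from the
    reference table."""

    residues: dict[int, ResidueShifts] = field(default_factory=dict)
    gaps: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class CsdThresholds:
    """Full-element deviation magnitudes and the classification fraction.

    ``helix_full``/``sheet_full`` are (Ca, CO, Ha) signed deviations of fully
    formed elements; a residue is called when each available smoothed
    deviation reaches ``call_fraction`` of the full magnitude with the right
    sign.  ``smoothing_window`` is a centered moving average (odd, in
    residues; 1 disables smoothing).
    """

    helix_full: tuple[float, float, float] = (2.6, 1.7, -0.38)
    sheet_full: tuple[float, float, float] = (-1.4, -1.4, 0.38)
    call_fraction: float = 0.5
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.call_fraction <= 1:
            raise ValueError("call_fraction must lie in (0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def secondary_shifts(
    observed: Iterable[ShiftRecord],
    reference: Optional[RandomCoilTable] = None,
) -> SecondaryShiftProfile:
    """Deviations delta = observed - random coil, per residue and nucleus.

    Only Ca, CO (atom "C") and Ha shifts are used; other atoms are ignored
    with a warning.  Residues whose name is missing from the reference table
    are reported as gaps, not errors.
    """
    reference = reference or builtin_random_coil_table()
    profile = SecondaryShiftProfile()
    ignored: set[str] = set()
    for rec in observed:
        nucleus = _ATOM_TO_NUCLEUS.get(rec.atom.atom_name)
        if nucleus is None:
            ignored.add(rec.atom.atom_name)
            continue
        rc = reference.get(rec.atom.residue_name, nucleus)
        num = rec.atom.residue_number
        if rc is None:
            if num not in profile.gaps:
                profile.gaps.append(num)
            continue
        entry = profile.residues.setdefault(
            num, ResidueShifts(num, rec.atom.residue_name)
        )
        entry.delta[nucleus] = rec.shift - rc
    if ignored:
        warnings.warn(
            f"ignored atoms outside CA/C/HA: {', '.join(sorted(ignored))}",
            stacklevel=2,
        )
    return profile


def _smooth(profile: SecondaryShiftProfile, window: int) -> dict[int, dict[str, float]]:
    """Centered moving average per nucleus; the window shrinks at gaps/edges
    to whichever neighbors actually carry that nucleus."""
    half = window // 2
    smoothed: dict[int, dict[str, float]] = {}
    for num in profile.residues:
        out: dict[str, float] = {}
        for nuc in _NUCLEI:
            vals = [
                profile.residues[n].delta[nuc]
                for n in range(num - half, num + half + 1)
                if n in profile.residues and nuc in profile.residues[n].delta
            ]
            if nuc in profile.residues[num].delta:
                out[nuc] = sum(vals) / len(vals)
        smoothed[num] = out
    return smoothed


def classify_residues(
    profile: SecondaryShiftProfile,
    thresholds: Optional[CsdThresholds] = None,
) -> SecondaryShiftProfile:
    """Assign helix/sheet/coil labels to a deviation profile (in place).

    After smoothing, a residue is helix when every available deviation
    reaches ``call_fraction`` of the full-helix magnitude with helix signs
    (Ca, CO positive; Ha negative); sheet analogously.  Residues with fewer
    than two nuclei are labeled insufficient.
    """
    thresholds = thresholds or CsdThresholds()
    smoothed = _smooth(profile, thresholds.smoothing_window)
    f = thresholds.call_fraction

    # tiny slack so residues at the exact boundary are called despite
    # floating-point error in the observed-minus-reference subtraction
    eps = 1e-9

    def reaches(delta: Mapping[str, float], full: tuple[float, float, float]) -> bool:
        for nuc, target in zip(_NUCLEI, full):
            if nuc not in delta:
                continue
            needed = f * target
            if target >= 0:
                if delta[nuc] < needed - eps:
                    return False
            elif delta[nuc] > needed + eps:
                return False
        return True

    for num, entry in profile.residues.items():
        delta = smoothed[num]
        if len(delta) < 2:
            entry.label = StructureLabel.INSUFFICIENT
        elif reaches(delta, thresholds.helix_full):
            entry.label = StructureLabel.HELIX
        elif reaches(delta, thresholds.sheet_full):
            entry.label = StructureLabel.SHEET
        else:
            entry.label = StructureLabel.COIL
    return profile
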