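"""Domain types shared by every stage of the immersion-depth pipeline.

The pipeline analyses a micelle-bound peptide by NMR: per-proton peak-height
decays are fitted to mono-exponentials, solvent-PRE slopes are extracted from
a paramagnetic (Gd-chelate) titration, converted to immersion depths below the
micelle surface, and finally to center-referenced distance restraints for
structure calculation.  These dataclasses are the currency between stages;
each validates its own invariants at construction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class MicelleDepthError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MicelleDepthError):
    """A tabular input file is malformed (missing column, bad header)."""


class ParseError(MicelleDepthError):
    """A cell in a tabular input could not be parsed; carries the line number."""


class FitError(MicelleDepthError):
    """A least-squares fit failed or produced an unphysical result."""


class DomainError(MicelleDepthError):
    """An argument lies outside the mathematical domain of an operation."""


class DesignError(MicelleDepthError):
    """An experimental design is insufficient (too few points/concentrations)."""


@dataclass(frozen=True, order=True)
class AtomRef:
    """A single NMR-observable atom, in full-length protein numbering.

    Residue numbers follow the full-length mouse CGI-58 convention
    (Val10 = 10); no re-indexing to peptide-local numbering is done anywhere,
    so outputs stay comparable to the deposited assignments.
    """

    residue_number: int
    residue_name: str
    atom_name: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "residue_name", self.residue_name.strip().upper())
        object.__setattr__(self, "atom_name", self.atom_name.strip().upper())

    def __str__(self) -> str:  # e.g. "TRP21 HE1"
        return f"{self.residue_name}{self.residue_number} {self.atom_name}"


@dataclass
class DecaySeries:
    """One proton's peak heights over a list of relaxation delays.

    ``condition_label`` distinguishes experiments sharing an atom: a Gd
    concentration tag during a titration, or "T1"/"T2" for plain relaxation.
    """

    atom: AtomRef
    condition_label: str
    delays: Sequence[float]          # seconds, strictly increasing
    intensities: Sequence[float]     # peak heights, arbitrary units
    noise_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.delays = [float(t) for t in self.delays]
        self.intensities = [float(v) for v in self.intensities]
        if len(self.delays) != len(self.intensities):
            raise ValueError(
                f"{self.atom}: {len(self.delays)} delays vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.delays) < 3:
            raise ValueError(f"{self.atom}: need >= 3 points, got {len(self.delays)}")
        if any(t <= 0 for t in self.delays):
            raise ValueError(f"{self.atom}: delays must be > 0")
        if any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise ValueError(f"{self.atom}: delays must be strictly increasing")

    def __len__(self) -> int:
        return len(self.delays)


@dataclass
class RateFit:
    """A fitted mono-exponential rate (R1 or R2) with its standard errors.

    ``1/rate`` is the corresponding relaxation time (T1 or T2); which one is
    a property of the experiment, not of the fit.
    """

    atom: AtomRef
    rate: float              # s^-1
    amplitude: float         # intensity units
    rate_stderr: float       # s^-1
    amplitude_stderr: float  # intensity units
    residual_rms: float      # intensity units
    n_points: int

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"{self.atom}: rate must be > 0, got {self.rate}")
        if self.rate_stderr < 0 or self.amplitude_stderr < 0:
            raise ValueError(f"{self.atom}: standard errors must be >= 0")
        if self.n_points < 3:
            raise ValueError(f"{self.atom}: n_points must be >= 3")

    @property
    def relaxation_time(self) -> float:
        """T1 or T2 in seconds (the caller knows which experiment this was)."""
        return 1.0 / self.rate


@dataclass
class HetNoeValue:
    """Heteronuclear NOE ratio (saturated/reference) for one backbone amide."""

    atom: AtomRef
    ratio: float
    stderr: float

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError(f"{self.atom}: stderr must be >= 0")


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift in ppm."""

    atom: AtomRef
    shift: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError(f"{self.atom}: shift must be finite")


@dataclass(frozen=True)
class MicelleModel:
    """Hydrodynamic radius of the micelle-peptide particle, in Å.

    ``free_radius`` optionally records the radius of the detergent micelle
    without peptide (a smaller particle), for reporting only.
    """

    radius: float
    free_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("micelle radius must be > 0")
        if self.free_radius is not None and not self.free_radius > 0:
            raise ValueError("free_radius must be > 0 when given")


@dataclass(frozen=True)
class PreConstants:
    """Calibration constants of the solvent-PRE depth model and restraint rules.

    The depth model is pre = k / (g + depth)^3, i.e. the PRE slope of a proton
    a distance ``depth`` below the micelle surface falls off with the cube of
    its separation from the solvent, offset by ``g``.  ``k`` carries the unit
    s^-1 mM^-1 Å^3 (the s^-1 implied by the PRE slope unit).

    ``cutoff_distance`` is the center distance beyond which a proton is
    treated as solvent-exposed and gets only a lower-bound restraint;
    ``bound_width`` the half-width of bounded restraints; ``weight`` the
    restraint weight relative to NOE-derived restraints.
    """

    g: float = 7.98                # Å
    k: float = 253.0               # s^-1 mM^-1 Å^3
    cutoff_distance: float = 28.0  # Å
    bound_width: float = 2.0       # Å
    weight: float = 0.30           # fraction of NOE weight

    def __post_init__(self) -> None:
        if not self.g > 0 or not self.k > 0:
            raise ValueError("g and k must be > 0")
        if not self.cutoff_distance > 0:
            raise ValueError("cutoff_distance must be > 0")
        if not self.bound_width > 0:
            raise ValueError("bound_width must be > 0")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")

    @property
    def surface_pre(self) -> float:
        """PRE slope of a proton exactly at the micelle surface: k/g^3."""
        return self.k / self.g ** 3


class RestraintKind(str, Enum):
    BOUNDED = "bounded"
    LOWER_ONLY = "lower_only"


@dataclass(frozen=True)
class DepthRestraint:
    """A center-referenced distance restraint ready for export.

    ``target_distance`` is the distance from the proton to the micelle center.
    Bounded restraints carry symmetric lower/upper limits; lower-only
    restraints (solvent-exposed protons) carry no upper limit.
    """

    atom: AtomRef
    target_distance: float
    lower: Optional[float]
    upper: Optional[float]
    weight: float
    kind: RestraintKind

    def __post_init__(self) -> None:
        if self.kind is RestraintKind.BOUNDED:
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.atom}: bounded restraint needs both limits")
            if not (self.lower <= self.target_distance <= self.upper):
                raise ValueError(
                    f"{self.atom}: target {self.target_distance} outside "
                    f"[{self.lower}, {self.upper}]"
                )
        elif self.kind is RestraintKind.LOWER_ONLY:
            if self.upper is not None:
                raise ValueError(f"{self.atom}: lower_only restraint must not have an upper limit")
            if self.lower is None:
                raise ValueError(f"{self.atom}: lower_only restraint needs a lower limit")


@dataclass
class PreRecord:
    """Per-proton solvent-PRE slope from the linear R1-vs-concentration fit."""

    atom: AtomRef
    pre: float               # s^-1 mM^-1
    r1_dia: float            # s^-1, diamagnetic intercept at 0 mM
    pre_stderr: float        # s^-1 mM^-1
    n_concentrations: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_concentrations < 3:
            raise ValueError(f"{self.atom}: need >= 3 concentrations")
        if self.pre_stderr < 0:
            raise ValueError(f"{self.atom}: pre_stderr must be >= 0")


@dataclass
class DepthResult:
    """Immersion depth and center distance for one proton.

    A non-positive PRE slope has no finite depth under the model; such protons
    are flagged with ``depth = -inf`` and ``distance_to_center = +inf``
    (rendered as "> cutoff" in human-readable output) and ``within_cutoff``
    False, which routes them to a lower-only restraint downstream.
    """

    atom: AtomRef
    depth: float              # Å below the micelle surface; -inf sentinel
    distance_to_center: float  # Å; +inf sentinel
    depth_stderr: float        # Å, first-order propagation from pre_stderr
    within_cutoff: bool


@dataclass(frozen=True)
class TitrationDesign:
    """Concentration grid (mM) and relaxation-delay grid (s) of a titration."""

    concentrations: Sequence[float]
    delays: Sequence[float]

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.concentrations)
        delays = tuple(float(t) for t in self.delays)
        object.__setattr__(self, "concentrations", concs)
        object.__setattr__(self, "delays", delays)
        if len(set(concs)) < 3 or 0.0 not in concs:
            raise ValueError("need >= 3 distinct concentrations including 0")
        if len(delays) < 3 or any(t <= 0 for t in delays):
            raise ValueError("delays must be > 0, length >= 3")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("delays must be strictly increasing")


@dataclass(frozen=True)
class MobilityThresholds:
    """Thresholds separating rigid (micelle-anchored) from flexible residues.

    T2 below ~100 ms signals tumbling like a large particle (micelle-bound);
    a heteronuclear NOE well below the rigid-limit ~0.8 signals fast internal
    motion.  ``min_run_length`` suppresses isolated one- or two-residue calls.
    """

    t2_rigid_max: float = 0.100      # s
    hetnoe_rigid_min: float = 0.5    # dimensionless
    min_run_length: int = 3          # residues

    def __post_init__(self) -> None:
        if not self.t2_rigid_max > 0:
            raise ValueError("t2_rigid_max must be > 0")
        if not 0 <= self.hetnoe_rigid_min <= 1:
            raise ValueError("hetnoe_rigid_min must lie in [0, 1]")
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")


class MobilityLabel(str, Enum):
    RIGID = "rigid"
    FLEXIBLE = "flexible"
    UNKNOWN = "unknown"


@dataclass
class MobilitySegmentation:
    """Per-residue rigid/flexible labels plus the maximal rigid runs."""

    per_residue_label: dict[int, MobilityLabel] = field(default_factory=dict)
    rigid_runs: list[tuple[int, int]] = field(default_factory=list)
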