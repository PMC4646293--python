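"""Solvent-PRE extraction, immersion-depth conversion, and restraint
generation.

A water-soluble, inert gadolinium chelate raises the longitudinal relaxation
rate of every proton linearly with its concentration; the slope (the solvent
PRE, s^-1 mM^-1) falls off with how deeply the proton sits below the micelle
surface.  The calibrated depth model is

    pre = k / (g + depth)^3        <=>        depth = (k / pre)^(1/3) - g

with offset g (Å) and scale k (s^-1 mM^-1 Å^3).  Distance to the micelle
center is the micelle hydrodynamic radius minus the depth; protons farther
from the center than a cutoff are treated as solvent-exposed and restrained
from below only.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import constants as sc
from scipy.stats import linregress

from .types import (
    DepthResult,
    DepthRestraint,
    DesignError,
    DomainError,
    MicelleModel,
    PreConstants,
    PreRecord,
    RateFit,
    RestraintKind,
)

__all__ = [
    "extract_pre",
    "depth_from_pre",
    "pre_from_depth",
    "distances_to_center",
    "generate_restraints",
    "hydrodynamic_radius",
]


def extract_pre(rates: Mapping[float, RateFit]) -> PreRecord:
    """Ordinary least-squares line R1(c) = r1_dia + pre * c for one atom.

    ``rates`` maps Gd concentration (mM) to the fitted longitudinal rate at
    that concentration.  The slope is the solvent PRE; its standard error and
    r^2 come from the regression.  A negative slope is physically spurious
    but is kept (noise does this for solvent-exposed protons); downstream
    stages route it to the solvent-exposed branch.
    """
    if len(rates) < 3:
        raise DesignError(f"need >= 3 concentrations, got {len(rates)}")
    atoms = {fit.atom for fit in rates.values()}
    if len(atoms) != 1:
        raise ValueError(f"rates mix atoms: {sorted(map(str, atoms))}")
    (atom,) = atoms

    conc = np.array(sorted(rates), dtype=float)
    r1 = np.array([rates[c].rate for c in conc])
    res = linregress(conc, r1)
    rvalue = float(res.rvalue)
    return PreRecord(
        atom=atom,
        pre=float(res.slope),
        r1_dia=float(res.intercept),
        pre_stderr=float(res.stderr),
        n_concentrations=len(conc),
        r_squared=rvalue * rvalue,
    )


def depth_from_pre(pre: float, constants: Optional[PreConstants] = None) -> float:
    """Immersion depth (Å below the micelle surface) from a PRE slope.

    depth = (k/pre)^(1/3) - g.  Negative depths (proton effectively outside
    the surface) are returned as-is; callers flag them.  A non-positive PRE
    has no finite depth and raises :class:`DomainError`.
    """
    constants = constants or PreConstants()
    if not pre > 0:
        raise DomainError(f"PRE must be > 0 for a finite depth, got {pre}")
    return (constants.k / pre) ** (1.0 / 3.0) - constants.g


def pre_from_depth(depth: float, constants: Optional[PreConstants] = None) -> float:
    """Forward model: PRE slope of a proton ``depth`` Å below the surface."""
    constants = constants or PreConstants()
    if not depth > -constants.g:
        raise DomainError(f"depth must exceed -g = {-constants.g} Å, got {depth}")
    return constants.k / (depth + constants.g) ** 3


def distances_to_center(
    pres: Sequence[PreRecord],
    micelle: MicelleModel,
    constants: Optional[PreConstants] = None,
) -> list[DepthResult]:
    """Convert PRE records to immersion depths and center distances.

    The depth standard error is first-order propagation of the PRE slope
    error through the depth model: |d(depth)/d(pre)| * pre_stderr =
    (1/3) (k/pre)^(1/3) / pre * pre_stderr.  Non-positive PRE slopes have no
    finite depth; they are reported with sentinel depth -inf / distance +inf
    and ``within_cutoff`` False.
    """
    constants = constants or PreConstants()
    results: list[DepthResult] = []
    for rec in pres:
        if rec.pre > 0:
            depth = depth_from_pre(rec.pre, constants)
            distance = micelle.radius - depth
            stderr = (
                (1.0 / 3.0)
                * (constants.k / rec.pre) ** (1.0 / 3.0)
                / rec.pre
                * rec.pre_stderr
            )
            within = distance <= constants.cutoff_distance
        else:
            depth, distance, stderr, within = -math.inf, math.inf, math.inf, False
        results.append(
            DepthResult(
                atom=rec.atom,
                depth=depth,
                distance_to_center=distance,
                depth_stderr=stderr,
                within_cutoff=within,
            )
        )
    return results


def generate_restraints(
    results: Sequence[DepthResult],
    constants: Optional[PreConstants] = None,
) -> list[DepthRestraint]:
    """Turn depth results into center-referenced distance restraints.

    Protons within the cutoff get bounded restraints [r - w, r + w] at the
    configured weight (w = ``bound_width``); protons beyond the cutoff but
    with a finite distance get a lower-only restraint at
    max(cutoff, r - w); protons with no finite distance (non-positive PRE)
    get a lower-only restraint at the cutoff itself.  Input order is
    preserved.
    """
    constants = constants or PreConstants()
    w = constants.bound_width
    restraints: list[DepthRestraint] = []
    for res in results:
        r = res.distance_to_center
        if res.within_cutoff:
            restraints.append(
                DepthRestraint(
                    atom=res.atom,
                    target_distance=r,
                    lower=r - w,
                    upper=r + w,
                    weight=constants.weight,
                    kind=RestraintKind.BOUNDED,
                )
            )
        else:
            lower = (
                max(constants.cutoff_distance, r - w)
                if math.isfinite(r)
                else constants.cutoff_distance
            )
            restraints.append(
                DepthRestraint(
                    atom=res.atom,
                    target_distance=r if math.isfinite(r) else lower,
                    lower=lower,
                    upper=None,
                    weight=constants.weight,
                    kind=RestraintKind.LOWER_ONLY,
                )
            )
    return restraints


def hydrodynamic_radius(
    diffusion_coefficient: float, temperature: float, viscosity: float
) -> float:
    """Stokes-Einstein hydrodynamic radius in Å.

    r = k_B T / (6 pi eta D) with D in m^2 s^-1, T in K, eta in Pa s.
    """
    if diffusion_coefficient <= 0 or temperature <= 0 or viscosity <= 0:
        raise DomainError("diffusion coefficient, temperature and viscosity must be > 0")
    r_m = sc.k * temperature / (6.0 * math.pi * viscosity * diffusion_coefficient)
    return r_m * 1e10
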