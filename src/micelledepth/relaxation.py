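"""Mono-exponential relaxation fitting, heteronuclear NOE, and mobility
segmentation.

Peak heights of a pseudo-3D relaxation series decay as I(t) = A exp(-R t);
the two-parameter model (no offset) matches peak-height decays, where an
offset would be unidentifiable on the 8-12 point delay grids typical of these
experiments.  Segmentation combines transverse relaxation times (short T2 =
micelle-bound, tumbling like a large particle) with heteronuclear NOE ratios
(high = rigid backbone) into per-residue rigid/flexible labels.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import curve_fit

from .types import (
    AtomRef,
    DecaySeries,
    DomainError,
    FitError,
    HetNoeValue,
    MobilityLabel,
    MobilitySegmentation,
    MobilityThresholds,
    RateFit,
)

__all__ = [
    "fit_monoexponential",
    "fit_relaxation_collection",
    "compute_hetnoe",
    "segment_mobility",
]


def _model(t: np.ndarray, amplitude: float, rate: float) -> np.ndarray:
    return amplitude * np.exp(-rate * t)


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initial (amplitude, rate) from linear regression of log(I) on t.

    Only points with positive intensity enter the regression; if fewer than
    two remain, fall back to a crude guess from the first point and the grid
    span.
    """
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        rate0 = max(-slope, 1e-6)
        amp0 = math.exp(intercept)
    else:
        amp0 = abs(y[0]) if y[0] != 0 else 1.0
        rate0 = 1.0 / (t[-1] - t[0])
    return amp0, rate0


def fit_monoexponential(series: DecaySeries) -> RateFit:
    """Least-squares fit of I(t) = A exp(-R t) to one decay series.

    Initialization comes from the log-linear regression; the rate is bounded
    to be positive.  Standard errors are the square roots of the diagonal of
    the linearized (Jacobian-based) covariance at the optimum.

    Raises :class:`FitError` (carrying the atom label) on non-convergence or
    when the fitted rate is not positive.
    """
    t = np.asarray(series.delays, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    if np.ptp(y) == 0:
        raise FitError(f"{series.atom}: intensities are all equal; no decay to fit")
    if y[0] <= 0:
        raise FitError(f"{series.atom}: first intensity must be positive")

    amp0, rate0 = _loglinear_init(t, y)
    try:
        popt, pcov = curve_fit(
            _model,
            t,
            y,
            p0=(amp0, rate0),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"{series.atom}: mono-exponential fit did not converge") from exc

    amplitude, rate = popt
    if not rate > 0:
        raise FitError(f"{series.atom}: fitted rate {rate} is not positive")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    residuals = y - _model(t, *popt)
    return RateFit(
        atom=series.atom,
        rate=float(rate),
        amplitude=float(amplitude),
        rate_stderr=float(perr[1]) if np.isfinite(perr[1]) else 0.0,
        amplitude_stderr=float(perr[0]) if np.isfinite(perr[0]) else 0.0,
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        n_points=len(series),
    )


def fit_relaxation_collection(
    series_list: Iterable[DecaySeries],
) -> tuple[dict[AtomRef, RateFit], dict[AtomRef, str]]:
    """Fit every series of a single-condition experiment, one per atom.

    Returns ``(fits, failures)`` where ``failures`` maps atoms whose fits
    failed to the failure message; failures are collected, not fatal.  An atom
    appearing under two different condition labels is an error (the caller
    must split conditions first), as is an empty input.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no decay series supplied")
    seen: dict[AtomRef, str] = {}
    for s in series_list:
        if s.atom in seen and seen[s.atom] != s.condition_label:
            raise ValueError(
                f"{s.atom} appears under conditions {seen[s.atom]!r} and "
                f"{s.condition_label!r}; separate conditions before fitting"
            )
        seen[s.atom] = s.condition_label

    fits: dict[AtomRef, RateFit] = {}
    failures: dict[AtomRef, str] = {}
    for s in series_list:
        try:
            fits[s.atom] = fit_monoexponential(s)
        except (FitError, ValueError) as exc:
            failures[s.atom] = str(exc)
    return fits, failures


def compute_hetnoe(
    atom: AtomRef,
    saturated: float,
    reference: float,
    noise_sat: float = 0.0,
    noise_ref: float = 0.0,
) -> HetNoeValue:
    """Heteronuclear NOE ratio saturated/reference with propagated error.

    The first-order error is |ratio| * sqrt((sigma_sat/sat)^2 +
    (sigma_ref/ref)^2).  Negative ratios are physical (fast internal motion)
    and pass through unchanged.
    """
    if reference == 0:
        raise DomainError(f"{atom}: reference intensity is zero; ratio undefined")
    if noise_sat < 0 or noise_ref < 0:
        raise ValueError("noise estimates must be >= 0")
    ratio = saturated / reference
    if saturated == 0:
        stderr = abs(noise_sat / reference)
    else:
        stderr = abs(ratio) * math.sqrt(
            (noise_sat / saturated) ** 2 + (noise_ref / reference) ** 2
        )
    return HetNoeValue(atom=atom, ratio=ratio, stderr=stderr)


def _runs_of(labels: Mapping[int, MobilityLabel], which: MobilityLabel) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residue numbers carrying ``which``."""
    residues = sorted(r for r, lab in labels.items() if lab is which)
    runs: list[tuple[int, int]] = []
    for r in residues:
        if runs and r == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], r)
        else:
            runs.append((r, r))
    return runs


def segment_mobility(
    t2_fits: Mapping[AtomRef, RateFit],
    hetnoe: Mapping[AtomRef, HetNoeValue],
    thresholds: Optional[MobilityThresholds] = None,
) -> MobilitySegmentation:
    """Label residues rigid/flexible from T2 and heteronuclear NOE data.

    A residue is rigid iff every available criterion passes (T2 <=
    ``t2_rigid_max``; NOE ratio >= ``hetnoe_rigid_min``) and at least one is
    available; residues with no data are labeled unknown.  Rigid runs shorter
    than ``min_run_length`` are demoted to flexible, and the reported
    ``rigid_runs`` are recomputed from the final labels.  When a residue
    carries data on several atoms, the backbone amide (atom H) is
    authoritative.
    """
    thresholds = thresholds or MobilityThresholds()

    def per_residue(values: Mapping[AtomRef, object]) -> dict[int, object]:
        out: dict[int, object] = {}
        backbone: dict[int, bool] = {}
        for atom, val in values.items():
            res = atom.residue_number
            is_bb = atom.atom_name == "H"
            if res not in out or (is_bb and not backbone[res]):
                out[res] = val
                backbone[res] = is_bb
        return out

    t2_by_res = per_residue(t2_fits)
    noe_by_res = per_residue(hetnoe)

    labels: dict[int, MobilityLabel] = {}
    for res in sorted(set(t2_by_res) | set(noe_by_res)):
        checks: list[bool] = []
        fit = t2_by_res.get(res)
        if fit is not None:
            checks.append(fit.relaxation_time <= thresholds.t2_rigid_max)
        noe = noe_by_res.get(res)
        if noe is not None:
            checks.append(noe.ratio >= thresholds.hetnoe_rigid_min)
        if not checks:
            labels[res] = MobilityLabel.UNKNOWN
        else:
            labels[res] = MobilityLabel.RIGID if all(checks) else MobilityLabel.FLEXIBLE

    for start, end in _runs_of(labels, MobilityLabel.RIGID):
        if end - start + 1 < thresholds.min_run_length:
            for res in range(start, end + 1):
                labels[res] = MobilityLabel.FLEXIBLE

    return MobilitySegmentation(
        per_residue_label=labels,
        rigid_runs=_runs_of(labels, MobilityLabel.RIGID),
    )
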