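"""PRE extraction, depth conversion, restraint rules, Stokes-Einstein.

The central oracle: the closed-form inversion depth = (k/pre)^(1/3) - g with
micelle radius 30 Å must reproduce all eleven benchmark center distances to
the printed 0.1 Å after rounding.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micelledepth import (
    AtomRef,
    DecaySeries,
    DesignError,
    DomainError,
    MicelleModel,
    PreConstants,
    PreRecord,
    RateFit,
    RestraintKind,
    depth_from_pre,
    distances_to_center,
    extract_pre,
    fit_monoexponential,
    generate_restraints,
    hydrodynamic_radius,
    pre_from_depth,
)

ATOM = AtomRef(21, "TRP", "H")
MICELLE = MicelleModel(radius=30.0)
CONSTANTS = PreConstants()


def _rate(atom, rate):
    return RateFit(atom, rate, 100.0, 0.01, 0.1, 0.0, 10)


def _pre_record(atom, pre, stderr=0.0):
    return PreRecord(atom, pre, 1.0, stderr, 6, 1.0)


class TestTable1Oracle:
    """The mandatory benchmark inversion check."""

    def test_all_rows_reproduce_printed_distance(self, table1_rows):
        for atom, pre, printed in table1_rows:
            depth = depth_from_pre(pre, CONSTANTS)
            assert round(MICELLE.radius - depth, 1) == pytest.approx(printed)

    def test_all_rows_within_005_before_rounding(self, table1_rows):
        """Noiseless synthetic titrations built from the benchmark slopes,
        pushed through the whole extraction chain, land within 0.05 Å of the
        printed distances before rounding."""
        for atom, pre, printed in table1_rows:
            rates = {c: _rate(atom, 0.8 + pre * c) for c in (0, 2, 4, 6, 8, 10)}
            rec = extract_pre(rates)
            (res,) = distances_to_center([rec], MICELLE, CONSTANTS)
            assert abs(res.distance_to_center - printed) < 0.05


class TestExtractPre:
    def test_recovers_constructed_line_exactly(self):
        r1 = {0: 0.5, 2: 0.9676, 4: 1.4352, 6: 1.9028, 8: 2.3704, 10: 2.838}
        rec = extract_pre({c: _rate(ATOM, v) for c, v in r1.items()})
        assert rec.pre == pytest.approx(0.2338, abs=1e-12)
        assert rec.r1_dia == pytest.approx(0.5, abs=1e-12)
        assert rec.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope(self):
        rec = extract_pre({c: _rate(ATOM, 0.8) for c in (0, 2, 4)})
        assert rec.pre == pytest.approx(0.0, abs=1e-15)
        assert rec.r1_dia == pytest.approx(0.8)

    def test_too_few_concentrations(self):
        with pytest.raises(DesignError):
            extract_pre({0: _rate(ATOM, 0.5), 10: _rate(ATOM, 2.8)})

    def test_mixed_atoms_rejected(self):
        other = AtomRef(22, "LEU", "H")
        with pytest.raises(ValueError, match="mix"):
            extract_pre({0: _rate(ATOM, 0.5), 2: _rate(other, 0.9), 4: _rate(ATOM, 1.4)})


class TestDepthConversion:
    def test_trp21_depth(self):
        assert depth_from_pre(0.2338) == pytest.approx(2.29, abs=0.005)

    def test_surface_boundary(self):
        assert depth_from_pre(CONSTANTS.surface_pre) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_pre_rejected(self):
        for bad in (0.0, -0.1):
            with pytest.raises(DomainError):
                depth_from_pre(bad)

    def test_forward_model(self):
        assert pre_from_depth(0.0) == pytest.approx(CONSTANTS.surface_pre)
        assert pre_from_depth(2.29) == pytest.approx(0.2338, abs=5e-4)

    @pytest.mark.parametrize("depth", [0.1, 1.0, 5.0, 10.0])
    def test_round_trip_identity(self, depth):
        assert depth_from_pre(pre_from_depth(depth)) == pytest.approx(depth, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.005, max_value=0.49),
           st.floats(min_value=0.005, max_value=0.49))
    def test_strictly_decreasing_in_pre(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert depth_from_pre(lo) > depth_from_pre(hi)


class TestDistancesToCenter:
    def test_shallow_proton_beyond_cutoff(self):
        (res,) = distances_to_center([_pre_record(ATOM, 0.45)], MICELLE, CONSTANTS)
        assert res.distance_to_center == pytest.approx(29.7, abs=0.05)
        assert not res.within_cutoff

    def test_nonpositive_pre_sentinel(self):
        (res,) = distances_to_center([_pre_record(ATOM, -0.01)], MICELLE, CONSTANTS)
        assert math.isinf(res.distance_to_center) and not res.within_cutoff

    def test_empty_input(self):
        assert distances_to_center([], MICELLE, CONSTANTS) == []

    def test_stderr_propagation_formula(self):
        pre, sigma = 0.2338, 0.01
        (res,) = distances_to_center([_pre_record(ATOM, pre, sigma)], MICELLE, CONSTANTS)
        expected = (1 / 3) * (CONSTANTS.k / pre) ** (1 / 3) / pre * sigma
        assert res.depth_stderr == pytest.approx(expected, rel=1e-12)

    def test_monte_carlo_depth_stderr_calibration(self):
        """SD of depths recovered from noisy titrations matches the
        propagated depth_stderr within a factor of 1.5 (2% intensity noise,
        200 replicates)."""
        rng = np.random.default_rng(7)
        true_pre, r1_dia, amp = 0.2338, 0.8, 100.0
        concs = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
        delays = np.array([0.07, 0.15, 0.25, 0.35, 0.5, 0.75, 1.0, 2.0, 3.0, 5.0])
        depths, stderrs = [], []
        for _ in range(200):
            rates = {}
            for c in concs:
                y = amp * np.exp(-(r1_dia + true_pre * c) * delays)
                y = y * (1 + rng.normal(0, 0.02, y.size))
                rates[c] = fit_monoexponential(
                    DecaySeries(ATOM, f"{c:g}mM", delays.tolist(), y.tolist())
                )
            rec = extract_pre(rates)
            (res,) = distances_to_center([rec], MICELLE, CONSTANTS)
            depths.append(res.depth)
            stderrs.append(res.depth_stderr)
        ratio = np.std(depths) / np.mean(stderrs)
        assert 1 / 1.5 < ratio < 1.5


class TestGenerateRestraints:
    def test_bounded_restraint_from_benchmark_distance(self):
        (res,) = distances_to_center([_pre_record(ATOM, 0.2338)], MICELLE, CONSTANTS)
        (r,) = generate_restraints([res], CONSTANTS)
        assert r.kind is RestraintKind.BOUNDED
        assert r.lower == pytest.approx(25.7, abs=0.05)
        assert r.upper == pytest.approx(29.7, abs=0.05)
        assert r.weight == 0.3
        assert r.upper - r.lower == pytest.approx(2 * CONSTANTS.bound_width)

    def test_beyond_cutoff_lower_only_floored_at_cutoff(self):
        (res,) = distances_to_center([_pre_record(ATOM, 0.45)], MICELLE, CONSTANTS)
        (r,) = generate_restraints([res], CONSTANTS)
        assert r.kind is RestraintKind.LOWER_ONLY and r.upper is None
        # max(cutoff 28, 29.7 - 2) = 28.0
        assert r.lower == pytest.approx(28.0)

    def test_negative_pre_lower_only_at_cutoff(self):
        (res,) = distances_to_center([_pre_record(ATOM, -0.05)], MICELLE, CONSTANTS)
        (r,) = generate_restraints([res], CONSTANTS)
        assert r.kind is RestraintKind.LOWER_ONLY
        assert r.lower == CONSTANTS.cutoff_distance

    def test_counts_and_upper_bound_invariant(self, table1_rows):
        recs = [_pre_record(atom, pre) for atom, pre, _ in table1_rows]
        recs.append(_pre_record(AtomRef(33, "SER", "H"), 0.6))
        results = distances_to_center(recs, MICELLE, CONSTANTS)
        restraints = generate_restraints(results, CONSTANTS)
        n_bounded = sum(r.kind is RestraintKind.BOUNDED for r in restraints)
        assert n_bounded == sum(r.within_cutoff for r in results)
        for r in restraints:
            if r.kind is RestraintKind.BOUNDED:
                assert r.upper <= MICELLE.radius + CONSTANTS.bound_width


class TestHydrodynamicRadius:
    def test_free_micelle_round_trip(self):
        # D chosen so that r = 21 Å at 293 K in water
        from scipy.constants import k as kB

        D = kB * 293.0 / (6 * math.pi * 1.002e-3 * 21e-10)
        assert hydrodynamic_radius(D, 293.0, 1.002e-3) == pytest.approx(21.0, rel=1e-12)

    def test_doubling_d_halves_r(self):
        r1 = hydrodynamic_radius(1e-10, 293.0, 1.002e-3)
        r2 = hydrodynamic_radius(2e-10, 293.0, 1.002e-3)
        assert r1 == pytest.approx(2 * r2, rel=1e-12)

    def test_radius_vanishes_with_temperature(self):
        assert hydrodynamic_radius(1e-10, 1e-9, 1.002e-3) < 1e-6

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            hydrodynamic_radius(-1e-10, 293.0, 1e-3)
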