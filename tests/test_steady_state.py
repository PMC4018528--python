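"""Steady-state solvers: equilibrium partition, flux balance, fold changes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capinit import (
    ParameterRamp,
    SpeciesState,
    TABLE1_TOTALS,
    Totals,
    equilibrium_partition,
    flux_balance_steady_state,
    flux_balanced_kcat,
    fold_changes,
    simulate,
)


class TestEquilibriumPartition:
    def test_unfertilized_egg_concentrations(self, totals, rates):
        """The canonical totals and KDs reproduce the published partition
        (two-decimal uM precision)."""
        st_ = equilibrium_partition(totals, rates.kd1, rates.kd2)
        assert round(st_.complex_eb, 2) == 1.77
        assert round(st_.complex_eg, 2) == 0.36
        assert round(st_.fourebp_free, 2) == 1.90
        assert round(st_.eif4g_free, 2) == 1.79
        assert round(st_.eif4e_free, 2) == 0.02

    def test_equilibrium_and_conservation_residuals(self, totals, rates):
        s = equilibrium_partition(totals, rates.kd1, rates.kd2)
        r1 = s.eif4e_free * s.fourebp_free / s.complex_eb
        r2 = s.eif4e_free * s.eif4g_free / s.complex_eg
        assert abs(r1 - rates.kd1) / rates.kd1 < 1e-8
        assert abs(r2 - rates.kd2) / rates.kd2 < 1e-8
        assert s.total_eif4e == pytest.approx(totals.total_eif4e, abs=1e-10)
        assert s.total_eif4g == pytest.approx(totals.total_eif4g, abs=1e-10)
        assert s.total_4ebp == pytest.approx(totals.total_4ebp, abs=1e-10)

    def test_single_binder_matches_quadratic_closed_form(self, rates):
        """With no 4E-BP the system is one equilibrium whose solution is the
        standard quadratic in the complex concentration."""
        t = Totals(0.0, 2.15, 2.15)
        s = equilibrium_partition(t, rates.kd1, rates.kd2)
        et, gt, kd = 2.15, 2.15, rates.kd2
        b = et + gt + kd
        c2_quad = (b - math.sqrt(b * b - 4 * et * gt)) / 2
        assert s.complex_eb == 0.0
        assert s.complex_eg == pytest.approx(c2_quad, rel=1e-10)

    def test_vanishing_affinity_leaves_everything_free(self, totals):
        s = equilibrium_partition(totals, 1e6, 1e6)
        assert s.complex_eb < 1e-5 and s.complex_eg < 1e-5
        assert s.eif4e_free == pytest.approx(totals.total_eif4e, rel=1e-4)

    def test_rejects_nonpositive_kd(self, totals):
        with pytest.raises(ValueError):
            equilibrium_partition(totals, 0.0, 0.1)

    @pytest.mark.parametrize("kd1_scale", [1.0, 2.0, 8.0, 100.0])
    def test_weaker_4ebp_binding_frees_eif4e_for_eif4g(self, totals, rates, kd1_scale):
        """complex_eg is nondecreasing in KD1 at fixed everything else."""
        lo = equilibrium_partition(totals, rates.kd1, rates.kd2)
        hi = equilibrium_partition(totals, rates.kd1 * kd1_scale, rates.kd2)
        assert hi.complex_eg >= lo.complex_eg - 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(factor=st.floats(min_value=0.05, max_value=50.0))
    def test_scaling_invariance(self, factor):
        """Scaling all totals and both KDs by a common factor scales every
        species by that factor (the equilibria are first-order homogeneous)."""
        kd1, kd2 = 0.0236559, 0.10989
        base = equilibrium_partition(TABLE1_TOTALS, kd1, kd2)
        scaled = equilibrium_partition(
            Totals(3.67 * factor, 2.15 * factor, 2.15 * factor),
            kd1 * factor,
            kd2 * factor,
        )
        for name in ("eif4e_free", "fourebp_free", "eif4g_free", "complex_eb", "complex_eg"):
            assert getattr(scaled, name) == pytest.approx(
                getattr(base, name) * factor, rel=1e-7, abs=1e-12
            )


class TestFluxBalance:
    def test_fertilized_complex_eg_fold(self, totals, baseline, partition):
        fert = baseline.scaled({"k_off1": 8.0, "k_lys_4ebp": 32.5})
        s = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, fert)
        assert s.complex_eg / partition.complex_eg == pytest.approx(4.2, rel=0.05)

    def test_rapamycin_complex_eg_fold(self, totals, baseline, partition):
        rap = baseline.scaled({"k_lys_4ebp": 16.0})
        s = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, rap)
        assert s.complex_eg / partition.complex_eg == pytest.approx(2.58, rel=0.05)

    def test_no_synthesis_empties_4ebp(self, totals, baseline):
        p = baseline.replace(k_cat_4ebp=0.0)
        s = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, p)
        assert s.fourebp_free == 0.0 and s.complex_eb == 0.0

    def test_agrees_with_long_horizon_relaxation(self, totals, baseline, partition):
        """The closed-form flux-balance state matches the ODE system relaxed
        to t = 1e6 s under a step parameter change, within 1e-4 uM."""
        fert = baseline.scaled({"k_off1": 8.0, "k_lys_4ebp": 32.5})
        target = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, fert)
        traj = simulate(partition, ParameterRamp(fert, {}), [0.0, 1e6])
        relaxed = traj.state_at(-1)
        for name in ("eif4e_free", "fourebp_free", "eif4g_free", "complex_eb", "complex_eg"):
            assert abs(getattr(relaxed, name) - getattr(target, name)) < 1e-4

    def test_reduces_to_partition_when_balance_holds_there(self, totals, rates):
        """With k_cat chosen so synthesis balances degradation at the
        partition state, both solvers find the same state (to 1e-6 uM)."""
        kcat = flux_balanced_kcat(totals, rates)
        p = rates.replace(k_cat_4ebp=kcat)
        a = equilibrium_partition(totals, p.kd1, p.kd2)
        b = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, p)
        for name in ("eif4e_free", "fourebp_free", "eif4g_free", "complex_eb", "complex_eg"):
            assert abs(getattr(a, name) - getattr(b, name)) < 1e-6


class TestFoldChanges:
    def test_identity(self, partition):
        f = fold_changes(partition, partition)
        assert all(
            f[name] == pytest.approx(1.0)
            for name in f
            if not math.isnan(f[name])
        )

    def test_published_fold_presentation(self):
        ref = SpeciesState(0.02, 1.9, 1.79, 1.77, 0.36, 0.0)
        pert = SpeciesState(0.02, 1.9, 1.79, 1.77, 1.512, 0.0)
        assert fold_changes(ref, pert)["complex_eg"] == pytest.approx(4.2)

    def test_zero_reference_is_undefined_not_infinite(self):
        ref = SpeciesState(0.0, 1.0, 1.0, 1.0, 1.0, 0.0)
        pert = SpeciesState(0.5, 1.0, 1.0, 1.0, 1.0, 0.0)
        assert math.isnan(fold_changes(ref, pert)["eif4e_free"])
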