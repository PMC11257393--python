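import numpy as np
import pytest

import qsmemory as qs
from qsmemory import (activation_curves, memory_zone, component_swap,
                      instant_dissociation, run_to_steady, classify_activity)
from qsmemory.memory import ActivationCurve

COARSE = np.linspace(8.5, 10.5, 11)


@pytest.fixture(scope="module")
def base_zone(params, reference):
    curves = activation_curves(params, reference, N_start=10 ** 8.5, grid=COARSE)
    return memory_zone(curves, params, reference)


class TestMemoryZone:
    def test_zone_contains_the_intermediate_density(self, base_zone):
        """Growth from 10^8.5 cell/ml: history decides the outcome at 10^9.3."""
        assert not base_zone.is_empty
        assert base_zone.contains(9.3)

    def test_monotone_activation_along_each_curve(self, base_zone):
        for curve in base_zone.curves:
            on = curve.on_mask
            first_on = np.argmax(on) if on.any() else len(on)
            assert np.all(on[first_on:]), "activation must be monotone in N_max"

    def test_identical_initial_states_give_zero_width(self, params, reference):
        grid = np.linspace(9.2, 9.8, 5)
        curves = activation_curves(params, reference, N_start=10 ** 8.5,
                                   grid=grid, on_state=reference.off)
        zone = memory_zone(curves, params, reference,
                           on_state=reference.off)
        assert zone.width_log10 == 0.0 and zone.is_empty

    def test_width_bounded_by_grid_span(self, base_zone):
        assert 0.0 <= base_zone.width_log10 <= COARSE[-1] - COARSE[0]

    def test_noncontiguous_disagreement_warns(self, params, reference):
        grid = np.array([9.0, 9.2, 9.4, 9.6, 9.8])
        labs_on = ("ON", "OFF", "ON", "ON", "ON")
        labs_off = ("OFF", "OFF", "OFF", "ON", "ON")
        c_on = ActivationCurve(grid, np.array([1, 0, 1, 1, 1.0]), labs_on,
                               "ON", 10 ** 8.5)
        c_off = ActivationCurve(grid, np.array([0, 0, 0, 1, 1.0]), labs_off,
                                "OFF", 10 ** 8.5)
        with pytest.warns(UserWarning, match="non-contiguous"):
            memory_zone((c_on, c_off), params, reference, refine=False)

    def test_mismatched_grids_rejected(self, params, reference, base_zone):
        c_on, c_off = base_zone.curves
        shifted = ActivationCurve(c_off.log10_nmax + 0.1, c_off.final_g_norm,
                                  c_off.labels, "OFF", c_off.N_start)
        with pytest.raises(ValueError, match="grid"):
            memory_zone((c_on, shifted), params, reference)


class TestComponentSwap:
    def test_identity_swap(self, reference):
        assert component_swap(reference.on, reference.on,
                              ["I", "R", "RA", "C", "A"]) == reference.on

    def test_unknown_component_rejected(self, reference):
        with pytest.raises(ValueError, match="X"):
            component_swap(reference.on, reference.off, ["X"])

    def test_empty_components_rejected(self, reference):
        with pytest.raises(ValueError, match="non-empty"):
            component_swap(reference.on, reference.off, [])

    def test_full_swap_reproduces_off_outcome(self, params, reference):
        """Replacing every molecular component of the ON state by OFF values
        must land on the OFF attractor at every density (the residual G
        difference is a pure readout and is forgotten at steady state)."""
        swapped = component_swap(reference.on, reference.off,
                                 ["I", "R", "RA", "C", "A"])
        for log_n in (9.2, 9.8):
            st_sw = run_to_steady(params, swapped, 10 ** 8.5, 10 ** log_n,
                                  reference)
            st_off = run_to_steady(params, "OFF", 10 ** 8.5, 10 ** log_n,
                                   reference)
            assert classify_activity(st_sw, reference) == \
                classify_activity(st_off, reference)
            assert st_sw.G == pytest.approx(st_off.G, rel=1e-5)

    def test_dimer_and_luxi_carry_the_memory(self, params, reference, base_zone):
        """Swapping the dimer pool or LuxI to OFF values shrinks the memory
        zone more than swapping any of R, RA or A."""
        widths = {}
        for comp in ("C", "I", "R", "RA", "A"):
            state = component_swap(reference.on, reference.off, [comp])
            curves = activation_curves(params, reference, N_start=10 ** 8.5,
                                       grid=COARSE, on_state=state)
            zone = memory_zone(curves, params, reference, resolution=0.02,
                               on_state=state)
            widths[comp] = zone.width_log10
        base = base_zone.width_log10
        for major in ("C", "I"):
            for minor in ("R", "RA", "A"):
                assert base - widths[major] > base - widths[minor], (
                    f"swap {major} should lose more width than swap {minor}: "
                    f"{widths}")

    def test_off_cells_with_on_luxi_and_dimers_activate_earlier(
            self, params, reference):
        primed = component_swap(reference.off, reference.on, ["I", "C"])
        nc_primed = qs.critical_density(params, reference, initial=primed,
                                        N_start=10 ** 8.5, bracket=(8.6, 10.4),
                                        resolution=0.02)
        nc_off = qs.critical_density(params, reference, initial="OFF",
                                     N_start=10 ** 8.5, bracket=(8.6, 10.4),
                                     resolution=0.02)
        assert nc_primed < nc_off - 0.02


class TestInstantDissociation:
    def test_luxr_units_conserved(self, reference):
        out = instant_dissociation(reference.on, reference.off)
        assert out.total_luxr == pytest.approx(reference.on.total_luxr, rel=1e-12)

    def test_idempotent(self, reference):
        once = instant_dissociation(reference.on, reference.off)
        twice = instant_dissociation(once, reference.off)
        assert once == twice

    def test_activation_curve_nearly_unchanged(self, params, reference):
        """Disassembling the bound pools at dilution barely moves the
        activation curve of initially-ON cells."""
        diss = instant_dissociation(reference.on, reference.off)
        grid = np.linspace(8.5, 10.5, 21)
        c_ref, _ = activation_curves(params, reference, N_start=10 ** 8.5,
                                     grid=grid)
        c_diss, _ = activation_curves(params, reference, N_start=10 ** 8.5,
                                      grid=grid, on_state=diss)
        agree = np.mean(c_ref.on_mask == c_diss.on_mask)
        assert agree >= 0.95
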