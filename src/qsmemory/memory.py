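"""Memory-zone mapping: where does history decide the phenotype?

Two populations with identical kinetics but different pasts — one taken from
the activated (ON) steady state, one from the basal (OFF) state — are diluted
to the same starting density and grown to a range of final densities.  The
"memory zone" is the interval of final densities over which their outcomes
differ: initially-ON cells re-activate, initially-OFF cells do not.  The
module also dissects which molecular species carry that memory, by swapping
individual components of the initial condition between the two states and by
applying the instantaneous dimer/monomer-dissociation transformation used by
the reduced theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .circuit import SystemState, IntegrationError
from .params import KineticParameters
from .scenarios import (SteadyStateReference, run_to_steady, classify_activity,
                        normalized_g)

__all__ = [
    "ActivationCurve", "MemoryZone", "activation_curves", "memory_zone",
    "component_swap", "instant_dissociation", "SWAPPABLE",
]

SWAPPABLE = ("I", "R", "RA", "C", "A")


@dataclass(frozen=True)
class ActivationCurve:
    """Final normalized target-gene level vs carrying capacity, one history."""

    log10_nmax: np.ndarray
    final_g_norm: np.ndarray       # NaN where the integrator failed
    labels: tuple                  # 'ON' / 'OFF' / 'FAILED' per grid point
    initial: str
    N_start: float

    def __post_init__(self):
        object.__setattr__(self, "log10_nmax", np.asarray(self.log10_nmax, float))
        object.__setattr__(self, "final_g_norm", np.asarray(self.final_g_norm, float))
        if self.log10_nmax.shape != self.final_g_norm.shape:
            raise ValueError("grid and values must have matching shapes")

    @property
    def on_mask(self) -> np.ndarray:
        return np.array([lab == "ON" for lab in self.labels])


@dataclass(frozen=True)
class MemoryZone:
    """The density interval where the final state depends on the initial one."""

    lower: float      # log10 cell/ml: activation boundary of the ON-start curve
    upper: float      # log10 cell/ml: activation boundary of the OFF-start curve
    curves: tuple     # (ON-start curve, OFF-start curve)

    def __post_init__(self):
        if self.upper < self.lower:
            raise ValueError("memory-zone upper bound below lower bound")

    @property
    def width_log10(self) -> float:
        return self.upper - self.lower

    @property
    def width_linear(self) -> float:
        """Width in cell/ml, 10**upper - 10**lower."""
        return 10.0 ** self.upper - 10.0 ** self.lower

    @property
    def is_empty(self) -> bool:
        return self.width_log10 == 0.0

    def contains(self, log10_n: float) -> bool:
        return self.lower < log10_n < self.upper


def _curve(params, reference, initial_state, label, N_start, grid,
           rtol, atol) -> ActivationCurve:
    values, labels = [], []
    for log_nmax in grid:
        n_max = 10.0 ** log_nmax
        try:
            st = run_to_steady(params, initial_state, min(N_start, n_max), n_max,
                               reference, rtol=rtol, atol=atol)
        except IntegrationError as err:
            warnings.warn(f"integration failed at log10 N_max = {log_nmax:.3g}: {err}")
            values.append(np.nan)
            labels.append("FAILED")
            continue
        values.append(normalized_g(st, reference))
        labels.append(classify_activity(st, reference))
    return ActivationCurve(np.asarray(grid, float), np.asarray(values),
                           tuple(labels), label, N_start)


def activation_curves(
    params: KineticParameters,
    reference: SteadyStateReference,
    N_start: float = 10 ** 8.5,
    grid: np.ndarray | None = None,
    on_state: SystemState | None = None,
    off_state: SystemState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[ActivationCurve, ActivationCurve]:
    """Paired activation curves for initially-ON and initially-OFF populations.

    Each grid point is one growth-to-steady-state run from ``N_start`` to
    that carrying capacity, starting from the reference (or explicitly
    supplied) molecular state with the external signal reset to zero.
    Integrator failures mark single grid points, not the whole sweep.
    """
    if grid is None:
        grid = np.linspace(8.5, 10.5, 81)  # the published sweep range
    grid = np.asarray(grid, float)
    on0 = reference.on if on_state is None else on_state
    off0 = reference.off if off_state is None else off_state
    c_on = _curve(params, reference, on0, "ON", N_start, grid, rtol, atol)
    c_off = _curve(params, reference, off0, "OFF", N_start, grid, rtol, atol)
    return c_on, c_off


def _refine_boundary(params, reference, initial_state, N_start, lo, hi,
                     resolution, rtol, atol) -> float:
    """Bisect the OFF->ON switch of one curve to ``resolution`` log10 units."""
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        st = run_to_steady(params, initial_state, min(N_start, 10 ** mid),
                           10 ** mid, reference, rtol=rtol, atol=atol)
        if classify_activity(st, reference) == "ON":
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def memory_zone(
    curves: tuple[ActivationCurve, ActivationCurve],
    params: KineticParameters,
    reference: SteadyStateReference,
    resolution: float = 0.01,
    refine: bool = True,
    on_state: SystemState | None = None,
    off_state: SystemState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MemoryZone:
    """Locate the density interval where the two curves' classifications differ.

    A non-contiguous disagreement set raises a warning (the coarse grid
    straddles the boundaries poorly).  With ``refine`` the two boundaries are
    bisected down to ``resolution`` log10 units; an empty zone collapses both
    bounds onto the common activation boundary.
    """
    c_on, c_off = curves
    if not np.array_equal(c_on.log10_nmax, c_off.log10_nmax):
        raise ValueError("activation curves must share a grid")
    grid = c_on.log10_nmax
    disagree = c_on.on_mask ^ c_off.on_mask
    if disagree.any():
        idx = np.flatnonzero(disagree)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            warnings.warn("non-contiguous memory zone on the grid; "
                          "grid is probably too coarse")
    on0 = (reference.on if on_state is None else on_state)
    off0 = (reference.off if off_state is None else off_state)
    N_start = c_on.N_start

    def boundary(curve: ActivationCurve, state0: SystemState) -> float:
        mask = curve.on_mask
        if mask.all():
            return float(grid[0])
        if not mask.any():
            return float(grid[-1])
        i = int(np.argmax(mask))  # first ON point; assumes monotone activation
        if i == 0:
            return float(grid[0])
        if not refine:
            return 0.5 * (grid[i - 1] + grid[i])
        return _refine_boundary(params, reference, state0, N_start,
                                grid[i - 1], grid[i], resolution, rtol, atol)

    b_on = boundary(c_on, on0)
    b_off = boundary(c_off, off0)
    if not disagree.any() and abs(b_off - b_on) <= resolution:
        b_on = b_off  # classifications agree everywhere: zero-width zone
    return MemoryZone(lower=min(b_on, b_off), upper=max(b_on, b_off),
                      curves=(c_on, c_off))


def component_swap(
    base_state: SystemState,
    donor_state: SystemState,
    components,
) -> SystemState:
    """Replace the listed molecular components of ``base`` with donor values."""
    components = tuple(components)
    if not components:
        raise ValueError("components must be a non-empty subset of " + str(SWAPPABLE))
    unknown = [c for c in components if c not in SWAPPABLE]
    if unknown:
        raise ValueError(f"unknown component(s) {unknown}; expected subset of {SWAPPABLE}")
    return base_state.replace(**{c: getattr(donor_state, c) for c in components})


def instant_dissociation(
    on_state: SystemState,
    off_reference: SystemState,
    ahl_per_dimer: float = 2.0,
) -> SystemState:
    """Instantaneously disassemble the excess dimer/monomer pools.

    The bound-receptor excess over the OFF reference is converted to unbound
    units: each monomer releases one LuxR and one AHL, each dimer two LuxR
    and (by the default convention) two AHL.  Total LuxR units R + RA + 2C
    are conserved up to the OFF-reference substitution residue, and the
    transformation is idempotent.
    """
    d_ra = on_state.RA - off_reference.RA
    d_c = on_state.C - off_reference.C
    return on_state.replace(
        RA=off_reference.RA,
        C=off_reference.C,
        R=max(on_state.R + d_ra + 2.0 * d_c, 0.0),
        A=max(on_state.A + d_ra + ahl_per_dimer * d_c, 0.0),
    )
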