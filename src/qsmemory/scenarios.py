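"""Simulation protocols: ON/OFF characterization, growth runs, dilution,
activity classification and critical-density search.

The circuit's two reference phenotypes are obtained by growing a single cell
per ml (all molecular species zero) to saturation at two carrying capacities:
1e11 cell/ml yields the activated (ON) state, 1e7 cell/ml the basal (OFF)
state.  All downstream normalisation ("normalized G") is relative to these
two anchors, and the half-way point defines activity: a population is ON when
its target-gene product exceeds the midpoint of the OFF-to-ON span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .circuit import (SystemState, Trajectory, integrate,
                      steady_state, DEFAULT_RTOL, DEFAULT_ATOL)
from .params import KineticParameters

__all__ = [
    "SteadyStateReference", "DilutionEvent",
    "characterize_states", "run_scenario", "run_to_steady",
    "apply_dilution", "classify_activity", "normalized_g", "critical_density",
]

ON_DENSITY = 1e11   # cell/ml, carrying capacity of the ON characterization
OFF_DENSITY = 1e7   # cell/ml, carrying capacity of the OFF characterization


@dataclass(frozen=True)
class SteadyStateReference:
    """ON and OFF steady states plus per-species normalisation anchors."""

    on: SystemState
    off: SystemState

    def __post_init__(self):
        if not self.on.G > self.off.G:
            raise ValueError("ON-state G must exceed OFF-state G")
        if not self.on.I / self.off.I > 1.0:
            raise ValueError("ON-state LuxI must exceed OFF-state LuxI")

    @property
    def fold_change(self) -> float:
        """LuxI fold change I_ON / I_OFF."""
        return self.on.I / self.off.I

    def norm_constant(self, species: str) -> float:
        """ON-state value of a species (for 'divide by ON' normalisation)."""
        if species == "totR":
            return self.on.total_luxr
        return getattr(self.on, species)

    def state_for(self, label: str) -> SystemState:
        if label == "ON":
            return self.on
        if label == "OFF":
            return self.off
        raise ValueError(f"unknown state label {label!r}; expected 'ON' or 'OFF'")


@dataclass(frozen=True)
class DilutionEvent:
    """An abrupt transfer to fresh medium.

    Dilution replaces the density with ``N_0`` and (by default) resets the
    extracellular signal to zero; per-cell concentrations are untouched.
    """

    time: float = 0.0
    N_0: float = 1e6
    reset_external: bool = True

    def __post_init__(self):
        if not (math.isfinite(self.N_0) and self.N_0 > 0):
            raise ValueError(f"post-dilution density must be > 0, got {self.N_0!r}")


def apply_dilution(state: SystemState, event: DilutionEvent) -> SystemState:
    """Apply a dilution event: new density, optional external-signal reset."""
    if event.N_0 > state.N * (1 + 1e-12):
        raise ValueError(
            f"dilution cannot increase density ({state.N:.3g} -> {event.N_0:.3g})")
    kw = {"N": event.N_0}
    if event.reset_external:
        kw["Aex"] = 0.0
    return state.replace(**kw)


def characterize_states(
    params: KineticParameters,
    on_density: float = ON_DENSITY,
    off_density: float = OFF_DENSITY,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SteadyStateReference:
    """Compute the ON/OFF reference states by growth from 1 cell/ml.

    Both runs start with every molecular concentration at zero and a single
    cell per ml, and are integrated to the steady-state criterion at carrying
    capacities ``on_density`` and ``off_density``.
    """
    seed = SystemState(N=1.0)
    on, _ = steady_state(seed, params.with_(N_max=on_density), rtol=rtol, atol=atol)
    off, _ = steady_state(seed, params.with_(N_max=off_density), rtol=rtol, atol=atol)
    return SteadyStateReference(on=on, off=off)


def normalized_g(state: SystemState, reference: SteadyStateReference) -> float:
    """(G - G_OFF) / (G_ON - G_OFF)."""
    span = reference.on.G - reference.off.G
    if span == 0:
        raise ValueError("degenerate reference: G_ON equals G_OFF")
    return (state.G - reference.off.G) / span


def classify_activity(state: SystemState, reference: SteadyStateReference) -> str:
    """'ON' iff normalized G >= 0.5 (ties classified ON)."""
    return "ON" if normalized_g(state, reference) >= 0.5 else "OFF"


def _initial_state(
    initial, reference: SteadyStateReference | None, N_start: float,
) -> SystemState:
    if isinstance(initial, SystemState):
        base = initial
    else:
        if reference is None:
            raise ValueError("a SteadyStateReference is required for ON/OFF labels")
        base = reference.state_for(initial)
    return base.replace(N=N_start, Aex=0.0)


def run_scenario(
    params: KineticParameters,
    initial,
    N_start: float,
    N_max: float,
    t_end: float,
    reference: SteadyStateReference | None = None,
    output_resolution: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Grow a population from ``N_start`` to carrying capacity ``N_max``.

    ``initial`` is 'ON', 'OFF' (molecular concentrations taken from the
    reference, external signal reset to zero) or an explicit
    :class:`SystemState`.
    """
    if N_start > N_max * (1 + 1e-12):
        raise ValueError(f"N_start {N_start:.3g} exceeds N_max {N_max:.3g}")
    y0 = _initial_state(initial, reference, N_start)
    label = initial if isinstance(initial, str) else "custom"
    return integrate(y0, params.with_(N_max=N_max), t_end,
                     output_resolution=output_resolution, rtol=rtol, atol=atol,
                     meta={"initial": label, "N_start": N_start, "N_max": N_max})


def run_to_steady(
    params: KineticParameters,
    initial,
    N_start: float,
    N_max: float,
    reference: SteadyStateReference | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SystemState:
    """Like :func:`run_scenario` but integrate to the steady-state criterion."""
    if N_start > N_max * (1 + 1e-12):
        raise ValueError(f"N_start {N_start:.3g} exceeds N_max {N_max:.3g}")
    y0 = _initial_state(initial, reference, N_start)
    state, _ = steady_state(y0, params.with_(N_max=N_max), rtol=rtol, atol=atol)
    return state


def critical_density(
    params: KineticParameters,
    reference: SteadyStateReference,
    initial="OFF",
    N_start: float = 1.0,
    bracket: tuple[float, float] = (8.5, 10.5),
    resolution: float = 0.01,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Critical carrying capacity for activation, as log10(cell/ml).

    Bisects log10(N_max) between an OFF and an ON outcome: the returned value
    is where the steady-state normalized target-gene level crosses one half.
    ``initial`` and ``N_start`` select the protocol — growth from a single
    cell per ml with empty cells (the reference protocol), or growth of
    ON/OFF-initialised populations from a chosen starting density.
    """
    lo, hi = bracket
    if lo >= hi:
        raise ValueError(f"invalid bracket {bracket}")

    def is_on(log_nmax: float) -> bool:
        n_max = 10.0 ** log_nmax
        n0 = min(N_start, n_max)
        state = run_to_steady(params, initial, n0, n_max, reference,
                              rtol=rtol, atol=atol)
        return classify_activity(state, reference) == "ON"

    on_lo, on_hi = is_on(lo), is_on(hi)
    if on_lo == on_hi:
        raise ValueError(
            f"no activation crossing on bracket 10^{lo}..10^{hi} "
            f"(both {'ON' if on_lo else 'OFF'}); parameter set may be monostable")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if is_on(mid) == on_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
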