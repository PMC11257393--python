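"""Carry-over analysis of the deactivation phase.

After a dilution out of the activated state, each quorum-sensing biomolecule
relaxes back to its basal level on its own timescale: intracellular AHL
drains through the membrane within minutes, the dimer pool dissociates over
tens of minutes, and LuxI — lost only to cell division and slow intrinsic
degradation — persists for generations.  This module quantifies those
timescales: single-exponential fits ``C(t) = C_on * exp(-gamma t) + C_off``,
instantaneous maximum decay rates, time-to-baseline in generation units and
the width of the transient unbound-LuxR peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .circuit import Trajectory
from .params import KineticParameters
from .scenarios import SteadyStateReference, DilutionEvent, apply_dilution

__all__ = [
    "DecayFit", "GenerationsToOff", "fit_decay", "fit_decay_series",
    "max_decay_rate", "generations_to_off", "luxr_peak_fwhm",
    "deactivation_trajectory", "production_collapse_time", "total_luxr_trace",
]


@dataclass(frozen=True)
class DecayFit:
    """Fitted three-parameter exponential for one species' deactivation."""

    species: str
    amplitude: float        # C_on: decaying amplitude above the offset
    offset: float           # C_off: baseline
    gamma: float            # decay rate, 1/min
    window: tuple[float, float]
    rms: float              # residual root-mean-square in the fit units
    n_points: int

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError(f"fitted decay rate must be > 0, got {self.gamma}")

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model evaluated at absolute times ``t`` (same clock as the fit)."""
        return self.amplitude * np.exp(-self.gamma * (np.asarray(t) - self.window[0])) + self.offset


class GenerationsToOff(NamedTuple):
    """Time to reach a residual fraction of the ON-OFF span, in generations.

    ``lower_bound`` is True when the trajectory ended before the crossing, in
    which case ``generations`` is the elapsed span (a lower bound).
    """

    generations: float
    lower_bound: bool


def total_luxr_trace(traj: Trajectory, count_dimer_twice: bool = True) -> np.ndarray:
    """Total LuxR pool over time: R + RA + 2C (or R + RA + C)."""
    R, RA, C = traj.species("R"), traj.species("RA"), traj.species("C")
    return R + RA + (2.0 if count_dimer_twice else 1.0) * C


def _trace(traj: Trajectory, species: str) -> np.ndarray:
    return total_luxr_trace(traj) if species == "totR" else traj.species(species)


def _window_mask(t: np.ndarray, window: tuple[float, float] | None,
                 trace: np.ndarray) -> np.ndarray:
    if window is None:
        # Start at the post-dilution maximum: for monotone decays this is the
        # first sample; for species with a transient peak (unbound LuxR) it
        # skips the rising flank.
        i0 = int(np.argmax(trace))
        window = (float(t[i0]), float(t[-1]))
    return (t >= window[0]) & (t <= window[1]), window


def fit_decay(
    traj: Trajectory,
    species: str,
    window: tuple[float, float] | None = None,
    anchors: tuple[float, float] | None = None,
) -> DecayFit:
    """Least-squares fit of a single exponential to one species' decay.

    ``anchors = (on_value, off_value)`` pins the amplitude and offset to
    known steady-state concentrations, leaving only the rate free.  Without a
    window the fit starts at the post-dilution maximum of the trace.
    """
    return fit_decay_series(traj.time, _trace(traj, species), species=species,
                            window=window, anchors=anchors)


def fit_decay_series(
    time: np.ndarray,
    values: np.ndarray,
    species: str = "series",
    window: tuple[float, float] | None = None,
    anchors: tuple[float, float] | None = None,
) -> DecayFit:
    """:func:`fit_decay` on a bare (time, values) pair (e.g. synthetic traces)."""
    t = np.asarray(time, float)
    y = np.asarray(values, float)
    mask, window = _window_mask(t, window, y)
    tw, yw = t[mask], y[mask]
    if tw.size < 10:
        if y[-1] > y[0]:
            raise ValueError(
                f"{species} signal is increasing over the trace; not a decay")
        raise ValueError(f"fit window contains only {tw.size} samples (need >= 10)")
    if yw[-1] > yw[0]:
        raise ValueError(
            f"window [{window[0]:g}, {window[1]:g}] min shows an increasing "
            f"{species} signal; not a decay")
    ts = tw - tw[0]
    if anchors is not None:
        on_val, off_val = anchors
        amp = on_val - off_val

        def model(tt, g):
            return amp * np.exp(-g * tt) + off_val

        span = max(ts[-1], 1.0)
        p0 = [max(3.0 / span, 1e-6)]
        popt, _ = curve_fit(model, ts, yw, p0=p0, maxfev=20000)
        gamma = float(popt[0])
        resid = yw - model(ts, *popt)
        amplitude, offset = amp, off_val
    else:
        def model(tt, a, g, c):
            return a * np.exp(-g * tt) + c

        span = max(ts[-1], 1.0)
        p0 = [max(yw[0] - yw[-1], 1e-9), 3.0 / span, yw[-1]]
        popt, _ = curve_fit(model, ts, yw, p0=p0, maxfev=20000)
        amplitude, gamma, offset = (float(v) for v in popt)
        resid = yw - model(ts, *popt)
    if not (gamma > 0 and math.isfinite(gamma)):
        raise RuntimeError(f"decay fit for {species} did not converge to a positive rate")
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return DecayFit(species, amplitude, offset, gamma, window, rms, int(tw.size))


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    if x.size < width:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def max_decay_rate(
    traj: Trajectory,
    species: str,
    off_level: float | None = None,
    reference: SteadyStateReference | None = None,
    rel_floor: float = 1e-4,
) -> float | None:
    """Maximum instantaneous decay rate -d ln(C - C_off)/dt, 1/min.

    Computed by central differences on the 5-point-smoothed log excess over
    the baseline, restricted to the decaying segment after the trace maximum.
    Returns ``None`` (not applicable) when the species never rises
    appreciably above its OFF level.
    """
    y = _trace(traj, species)
    if off_level is None:
        if reference is None:
            raise ValueError("provide off_level or a SteadyStateReference")
        off_level = (reference.off.total_luxr if species == "totR"
                     else getattr(reference.off, species))
    excess = y - off_level
    peak = float(np.max(excess))
    if peak <= rel_floor * max(abs(off_level), 1e-12):
        return None
    i0 = int(np.argmax(excess))
    floor = peak * rel_floor
    seg = excess[i0:]
    t = traj.time[i0:]
    valid = seg > floor
    # keep the leading contiguous valid stretch
    stop = int(np.argmin(valid)) if not valid.all() else seg.size
    if stop < 3:
        return None
    logx = _smooth(np.log(seg[:stop]))
    rate = -np.gradient(logx, t[:stop])
    return float(np.max(rate))


def generations_to_off(
    traj: Trajectory,
    species: str,
    residual_fraction: float,
    reference: SteadyStateReference | None = None,
    on_level: float | None = None,
    off_level: float | None = None,
    doubling_time: float | None = None,
) -> GenerationsToOff:
    """Generations until the excess over OFF falls below ``residual_fraction``.

    The excess is normalised by the ON-OFF span; the crossing time (from the
    start of the trajectory, i.e. the dilution) is divided by the generation
    time ln2/k11.
    """
    if not 0.0 < residual_fraction < 1.0:
        raise ValueError("residual_fraction must lie strictly between 0 and 1")
    if doubling_time is None:
        doubling_time = traj.params.doubling_time
    if on_level is None or off_level is None:
        if reference is None:
            raise ValueError("provide a reference or explicit on/off levels")
        if species == "totR":
            on_level = reference.on.total_luxr if on_level is None else on_level
            off_level = reference.off.total_luxr if off_level is None else off_level
        else:
            on_level = getattr(reference.on, species) if on_level is None else on_level
            off_level = getattr(reference.off, species) if off_level is None else off_level
    span = on_level - off_level
    if span == 0:
        raise ValueError(f"degenerate ON-OFF span for {species}")
    frac = (_trace(traj, species) - off_level) / span
    below = frac < residual_fraction
    if not below.any():
        return GenerationsToOff((traj.time[-1] - traj.time[0]) / doubling_time, True)
    i = int(np.argmax(below))
    return GenerationsToOff((traj.time[i] - traj.time[0]) / doubling_time, False)


def luxr_peak_fwhm(
    traj: Trajectory,
    reference: SteadyStateReference,
    doubling_time: float | None = None,
) -> float:
    """Full width at half maximum of the unbound-LuxR excursion, in generations.

    Dimer dissociation after dilution transiently floods the cell with free
    receptor; the width of that peak (excess over the OFF level) measures how
    long the elevated-receptor memory persists.
    """
    if doubling_time is None:
        doubling_time = traj.params.doubling_time
    excess = traj.species("R") - reference.off.R
    peak = float(np.max(excess))
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    ipk = int(np.argmax(excess))
    above = excess >= half
    i0 = ipk
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = ipk
    while i1 < excess.size - 1 and above[i1 + 1]:
        i1 += 1
    return float(traj.time[i1] - traj.time[i0]) / doubling_time


def production_collapse_time(
    traj: Trajectory,
    params: KineticParameters | None = None,
    frac: float = 0.02,
) -> float:
    """First time the dimer level falls below ``frac * kdI``.

    Below this point the activated production term C/(kdI + C) contributes
    less than ~``frac`` of its maximum, so LuxI and G decay as bare
    exponentials — the validity condition of the single-exponential fit.
    """
    p = params if params is not None else traj.params
    C = traj.species("C")
    below = C <= frac * p.kdI
    if not below.any():
        return float(traj.time[-1])
    return float(traj.time[int(np.argmax(below))])


def deactivation_trajectory(
    params: KineticParameters,
    reference: SteadyStateReference,
    N_0: float = 1e6,
    t_end: float = 400.0,
    output_resolution: int = 2000,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """The canonical carry-over scenario: dilute the ON culture to ``N_0``.

    The ON steady state (grown to 1e11 cell/ml) is abruptly diluted, the
    external signal is reset to zero, and the population regrows toward the
    original carrying capacity while its molecular state relaxes to OFF.
    Tight tolerances keep the log-slope estimates smooth.
    """
    from .circuit import integrate  # local to avoid cycle at import time

    diluted = apply_dilution(reference.on, DilutionEvent(N_0=N_0))
    return integrate(diluted, params, t_end, output_resolution=output_resolution,
                     rtol=rtol, atol=atol,
                     meta={"scenario": "deactivation", "N_0": N_0})
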