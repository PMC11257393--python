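"""Closed-form theory of quorum-sensing phenotypic memory.

After dilution out of the activated state, the reduced model tracks only the
slow carriers of memory:

* per-cell LuxI relaxes as ``I(t) = I_OFF (1 + (FC-1) e^{-gamma t})`` —
  lost to dilution by division only;
* total LuxR relaxes as ``R(t) = R_OFF (1 + (FC-1) e^{-gamma_R t})`` with
  ``gamma_R = gamma + gamma_intrinsic``;
* extracellular AHL accumulates without degradation, fed by exponentially
  growing producers: ``A(t) = v_cell b I_OFF N_0 ((e^{gamma t}-1)/gamma +
  (FC-1) t)``.

The LuxI memory term ``xi(t) = gamma (FC-1) t / (e^{gamma t} - 1)`` is the
ratio of carry-over-driven to basal signal accumulation, and the overall
memory term ``Theta(t) = xi + (FC-1) e^{-gamma_R t} (1 + xi)`` adds the
receptor surplus.  Activation is a step function of the receptor-signal
binding rate crossing ``R_OFF * A_thresh``; solving for the crossing density
gives the critical densities ``N_C`` (naive cells) and ``N_C' <= N_C``
(previously activated cells), whose gap is the memory zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import AnalyticalParams

__all__ = [
    "luxi_decay", "accumulated_ahl", "xi", "total_luxr_decay", "theta",
    "binding_rate", "activation_time_numeric", "activation_time_approx",
    "critical_density_off", "critical_density_on", "critical_density_on_implicit",
    "memory_zone_width", "phase_diagram", "PhaseDiagram", "ACTIVATION_TIME_XTOL",
]

ACTIVATION_TIME_XTOL = 1e-3  # min


def luxi_decay(t, p: AnalyticalParams):
    """Per-cell LuxI of initially-ON cells, nM: I_OFF (1 + (FC-1) e^{-gamma t})."""
    t = np.asarray(t, float)
    out = p.I_OFF * (1.0 + (p.FC - 1.0) * np.exp(-p.gamma * t))
    return float(out) if out.ndim == 0 else out


def total_luxr_decay(t, p: AnalyticalParams):
    """Total LuxR of initially-ON cells, nM: R_OFF (1 + (FC-1) e^{-gamma_R t})."""
    t = np.asarray(t, float)
    out = p.R_OFF * (1.0 + (p.FC - 1.0) * np.exp(-p.gamma_R * t))
    return float(out) if out.ndim == 0 else out


def accumulated_ahl(t, p: AnalyticalParams, initially_on: bool = True):
    """Accumulated extracellular AHL at time ``t`` after dilution, nM.

    ``v_cell b I_OFF N_0 ((e^{gamma t}-1)/gamma + (FC-1) t)``; the second
    term (the LuxI carry-over contribution) is dropped for naive cells.
    """
    t = np.asarray(t, float)
    basal = np.expm1(p.gamma * t) / p.gamma
    carry = (p.FC - 1.0) * t if initially_on else 0.0
    out = p.v_cell * p.b * p.I_OFF * p.N_0 * (basal + carry)
    return float(out) if out.ndim == 0 else out


def xi(t, p: AnalyticalParams):
    """LuxI memory term: gamma (FC-1) t / (e^{gamma t} - 1).

    Continuous at t = 0 (removable singularity, value FC - 1); identically
    zero for naive cells (FC = 1).
    """
    t = np.asarray(t, float)
    x = p.gamma * t
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        ratio = np.where(x == 0.0, 1.0, x / np.expm1(x))
    out = (p.FC - 1.0) * ratio
    return float(out) if out.ndim == 0 else out


def theta(t, p: AnalyticalParams):
    """Overall memory term: xi(t) + (FC-1) e^{-gamma_R t} (1 + xi(t))."""
    t = np.asarray(t, float)
    x = xi(t, p)
    out = x + (p.FC - 1.0) * np.exp(-p.gamma_R * t) * (1.0 + x)
    return float(out) if np.ndim(out) == 0 else out


def binding_rate(t, p: AnalyticalParams, initially_on: bool = True):
    """Receptor-signal binding rate R(t) . A(t), threshold units.

    ``binding_constant * v_cell b R_OFF I_OFF (N(t)-N_0)/gamma (1+Theta(t))``
    with ``N(t) = N_0 e^{gamma t}`` and ``Theta = 0`` for naive cells.
    """
    t = np.asarray(t, float)
    growth = p.N_0 * np.expm1(p.gamma * t) / p.gamma   # (N(t) - N_0)/gamma
    mem = 1.0 + theta(t, p) if initially_on else 1.0
    out = p.binding_constant * p.v_cell * p.b * p.R_OFF * p.I_OFF * growth * mem
    return float(out) if np.ndim(out) == 0 else out


def _threshold(p: AnalyticalParams) -> float:
    return p.R_OFF * p.A_thresh


def activation_time_numeric(p: AnalyticalParams, initially_on: bool = True) -> float | None:
    """Earliest time the binding rate crosses the activation threshold, min.

    Returns ``None`` when the threshold is not reached within the growth
    horizon (the population never activates in the window considered).
    """
    thr = _threshold(p)
    f = lambda t: binding_rate(t, p, initially_on) - thr
    if f(0.0) >= 0.0:
        return 0.0
    # The rate need not be monotone (the memory term decays while growth
    # accelerates), so scan for the first sign change before root-polishing.
    grid = np.linspace(0.0, p.horizon, 2001)
    vals = binding_rate(grid, p, initially_on) - thr
    crossing = np.flatnonzero(vals >= 0.0)
    if crossing.size == 0:
        return None
    i = int(crossing[0])
    return float(brentq(f, grid[i - 1], grid[i], xtol=ACTIVATION_TIME_XTOL))


def activation_time_approx(p: AnalyticalParams) -> float:
    """Over-dilution approximation: (1/gamma) ln(gamma A_thresh / (N_0 v b I_OFF)).

    Valid when ``N_0 << N_C`` so that ``e^{gamma t} >> 1`` at crossing and the
    memory term is negligible.  Raises when the log argument is <= 1 (the
    population is already effectively at the critical density).
    """
    arg = p.gamma * p.A_thresh / (p.N_0 * p.v_cell * p.b * p.I_OFF * p.binding_constant)
    if arg <= 1.0:
        raise ValueError(
            f"over-dilution approximation invalid: N_0 = {p.N_0:.3g} is not far "
            f"below the critical density (log argument {arg:.3g} <= 1)")
    return math.log(arg) / p.gamma


def critical_density_off(p: AnalyticalParams) -> float:
    """Critical density of naive cells: gamma A_thresh / (v_cell b I_OFF) + N_0."""
    return (p.gamma * p.A_thresh
            / (p.binding_constant * p.v_cell * p.b * p.I_OFF) + p.N_0)


def critical_density_on(p: AnalyticalParams) -> float | None:
    """Critical density of previously activated cells, via the activation-time root.

    ``N_C' = N_0 e^{gamma t*}`` where ``t*`` is the initially-ON activation
    time; ``None`` when the cells never activate within the horizon.
    """
    t_act = activation_time_numeric(p, initially_on=True)
    if t_act is None:
        return None
    return p.N_0 * math.exp(p.gamma * t_act)


def critical_density_on_implicit(p: AnalyticalParams) -> float | None:
    """``N_C'`` from the implicit closed form, solved directly in density.

    ``N = N_0 + gamma A_thresh / (v b I_OFF (1 + Theta(ln(N/N_0)/gamma)))`` —
    an independent route to the same quantity used as a consistency check of
    the activation-time root.
    """
    k = p.gamma * p.A_thresh / (p.binding_constant * p.v_cell * p.b * p.I_OFF)

    def g(n):
        t = math.log(n / p.N_0) / p.gamma
        return n - p.N_0 - k / (1.0 + theta(t, p))

    n_hi = p.N_0 + k
    n_lo = p.N_0 * (1.0 + 1e-12)
    if g(n_lo) > 0 or g(n_hi) < 0:
        return None
    n = float(brentq(g, n_lo, n_hi, rtol=1e-12))
    if n > p.N_0 * math.exp(p.gamma * p.horizon):
        return None  # crossing lies beyond the growth window
    return n


def memory_zone_width(p: AnalyticalParams) -> float:
    """Width of the memory zone N_C - N_C', cell/ml.

    Equals ``gamma A_thresh/(v b I_OFF) * Theta(t*)/(1 + Theta(t*))`` with the
    memory term evaluated at the initially-ON activation time; 0 when the
    cells do not activate within the horizon (no memory effect expressible).
    """
    t_act = activation_time_numeric(p, initially_on=True)
    if t_act is None:
        return 0.0
    th = theta(t_act, p)
    k = p.gamma * p.A_thresh / (p.binding_constant * p.v_cell * p.b * p.I_OFF)
    return k * th / (1.0 + th)


def _vary(p: AnalyticalParams, axis: str, value: float) -> AnalyticalParams:
    if axis == "FC":
        return p.with_(FC=float(value))
    if axis == "doubling_time":
        return p.with_(gamma=math.log(2.0) / float(value))
    if axis == "b":
        return p.with_(b=float(value))
    if axis == "A_thresh":
        return p.with_(A_thresh=float(value))
    raise ValueError(f"unknown phase-diagram axis {axis!r}; "
                     "expected FC, doubling_time, b or A_thresh")


@dataclass(frozen=True)
class PhaseDiagram:
    """Region map over one cellular parameter and final cell density.

    Regions: 'I' both histories OFF, 'II' outcome depends on history (the
    memory zone), 'III' both ON.  ``boundaries`` holds per-axis-value
    ``(log10 N_C', log10 N_C)`` with NaN where activation never occurs within
    the horizon.
    """

    axis: str
    axis_values: np.ndarray
    log10_density: np.ndarray
    labels: np.ndarray          # shape (n_axis, n_density), dtype '<U3'
    boundaries: np.ndarray      # shape (n_axis, 2): log10 N_C', log10 N_C
    resolution: float

    def has_region(self, region: str) -> bool:
        return bool((self.labels == region).any())

    def zone_width_log10(self) -> np.ndarray:
        """Per-axis-value log10 width of region II (0 where absent)."""
        w = self.boundaries[:, 1] - self.boundaries[:, 0]
        w = np.where(np.isnan(w) | (w < self.resolution), 0.0, w)
        return w


def phase_diagram(
    p_base: AnalyticalParams,
    axis: str,
    axis_range: tuple[float, float],
    density_range: tuple[float, float] = (8.0, 11.0),
    n_axis: int = 41,
    n_density: int = 121,
    resolution: float = 0.01,
) -> PhaseDiagram:
    """Label OFF / memory / ON regions over a parameter-density plane.

    For each axis value the two critical densities are computed within the
    growth horizon; a memory region is drawn only when the boundaries are
    separated by at least ``resolution`` log10 units (the map's own
    resolution), matching how the zone closes up under over-dilution.
    """
    lo, hi = axis_range
    if axis == "FC" and lo < 1.0:
        raise ValueError("FC axis must start at >= 1")
    if lo <= 0 and axis != "FC":
        raise ValueError(f"{axis} axis range must be positive")
    axis_values = np.linspace(lo, hi, int(n_axis))
    dens = np.linspace(density_range[0], density_range[1], int(n_density))
    labels = np.full((axis_values.size, dens.size), "I", dtype="<U3")
    bounds = np.full((axis_values.size, 2), np.nan)
    for i, v in enumerate(axis_values):
        p = _vary(p_base, axis, v)
        t_off = activation_time_numeric(p, initially_on=False)
        n_on = critical_density_on(p)
        if n_on is None:
            continue  # no activation at all: whole column stays region I
        log_on = math.log10(n_on)
        if t_off is None:
            log_off = np.inf  # naive cells never activate in the window
        else:
            log_off = math.log10(critical_density_off(p))
        bounds[i] = (log_on, log_off if np.isfinite(log_off) else np.nan)
        if not np.isfinite(log_off) or (log_off - log_on) >= resolution:
            labels[i, (dens >= log_on) & (dens < log_off)] = "II"
        else:
            log_on = log_off  # indistinguishable at map resolution
        if np.isfinite(log_off):
            labels[i, dens >= log_off] = "III"
        elif not np.isfinite(log_off):
            pass  # ON-only activation: II extends to the top of the map
    return PhaseDiagram(axis, axis_values, dens, labels, bounds, resolution)
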