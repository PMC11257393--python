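"""Deterministic dynamics of the LuxR-LuxI positive-feedback circuit.

State variables (all per-cell concentrations in nM except the last two):

======  =====================================================
``I``   LuxI synthase protein
``R``   unbound LuxR receptor
``RA``  signal-bound LuxR monomer
``C``   LuxR dimer complex (the transcriptional activator)
``A``   intracellular AHL autoinducer
``Aex`` extracellular AHL (nM, shared medium)
``G``   quorum-sensing target gene product
``N``   cell density, cell/ml (logistic growth to ``N_max``)
======  =====================================================

The circuit is bistable over a window of carrying capacities: activated
production of LuxI and LuxR (via the dimer C) raises AHL synthesis, which
feeds back into dimer formation.  Intra- and extracellular AHL exchange
through the membrane at rate ``D``; the medium sees the cells through the
volume-fraction factor ``r * N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import KineticParameters

__all__ = [
    "SPECIES", "SystemState", "Trajectory", "IntegrationError",
    "rhs", "integrate", "steady_state",
]

SPECIES = ("I", "R", "RA", "C", "A", "Aex", "G", "N")
_MOLECULAR = slice(0, 7)  # every species except the density

#: CSV column names, in state order.
CSV_COLUMNS = ("I_nM", "R_nM", "RA_nM", "C_nM", "A_nM", "Aex_nM", "G_nM",
               "N_cells_per_ml")

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
STEADY_STATE_TOL = 1e-6   # nM/min, max |d/dt| over molecular species
STEADY_STATE_CAP = 1e6    # min


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the time of failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class SystemState:
    """One point of the circuit's state space."""

    I: float = 0.0
    R: float = 0.0
    RA: float = 0.0
    C: float = 0.0
    A: float = 0.0
    Aex: float = 0.0
    G: float = 0.0
    N: float = 1.0

    def __post_init__(self):
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"state component {name} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y, clip_tol: float = 1e-8) -> "SystemState":
        """Build from a raw solver vector.

        Tiny negative excursions within ``clip_tol`` (solver noise) are
        clipped to zero; anything more negative is a genuine error.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} components, got shape {y.shape}")
        if (y < -clip_tol).any():
            bad = SPECIES[int(np.argmin(y))]
            raise ValueError(f"state component {bad} is negative beyond tolerance: {y.min()}")
        return cls(**dict(zip(SPECIES, np.clip(y, 0.0, None))))

    def replace(self, **kw) -> "SystemState":
        d = {n: getattr(self, n) for n in SPECIES}
        d.update(kw)
        return SystemState(**d)

    @property
    def total_luxr(self) -> float:
        """Total LuxR protein units: R + RA + 2 C (two units per dimer)."""
        return self.R + self.RA + 2.0 * self.C


def _rhs_vec(t: float, y: np.ndarray, p: KineticParameters) -> np.ndarray:
    I, R, RA, C, A, Aex, G, N = y
    act = C / (p.kdI + C)
    act_R = C / (p.kdR + C)
    k8_RA = p.k8 if p.monomer_degradation else 0.0
    kG = p.k3 if p.g_activated_by_k3 else p.k4

    dI = p.k5 + p.k3 * act - p.k7 * I - p.k11 * I
    dR = p.k6 + p.k4 * act_R + p.k_m1 * RA - p.k1 * R * A - p.k8 * R - p.k11 * R
    dRA = (2.0 * p.k_m2 * C - 2.0 * p.k2 * RA * RA - p.k_m1 * RA
           + p.k1 * R * A - k8_RA * RA - p.k11 * RA)
    dC = p.k2 * RA * RA - p.k_m2 * C - p.k11 * C
    dA = (p.b * I - p.k1 * R * A + p.k_m1 * RA - p.D * (A - Aex)
          - p.k9 * A - p.k11 * A)
    dAex = p.r * p.D * N * (A - Aex) - p.k9 * Aex
    dG = p.k10 + kG * act - p.k7 * G - p.k11 * G
    dN = p.k11 * N * (1.0 - N / p.N_max)
    return np.array([dI, dR, dRA, dC, dA, dAex, dG, dN])


def rhs(state: SystemState, params: KineticParameters) -> np.ndarray:
    """Time derivatives of the circuit at ``state``, nM/min (density: cell/ml/min).

    The returned vector follows the ``SPECIES`` ordering.  Dimerisation
    consumes two bound monomers per complex and dissociation releases two;
    the target gene G is a pure readout (it feeds nothing back).
    """
    if not isinstance(state, SystemState):
        state = SystemState.from_array(np.asarray(state, dtype=float))
    return _rhs_vec(0.0, state.as_array(), params)


@dataclass
class Trajectory:
    """A time-resolved solution of the circuit ODEs."""

    time: np.ndarray                      # min, strictly increasing
    states: np.ndarray                    # (len(time), 8)
    params: KineticParameters
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.time.size, len(SPECIES)):
            raise ValueError(
                f"states shape {self.states.shape} does not match time grid "
                f"of length {self.time.size}"
            )
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def species(self, name: str) -> np.ndarray:
        """Time course of one species (or 'totR' for R + RA + 2C)."""
        if name == "totR":
            return (self.states[:, 1] + self.states[:, 2]
                    + 2.0 * self.states[:, 3])
        try:
            return self.states[:, SPECIES.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}; expected one of {SPECIES} or 'totR'")

    @property
    def final(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(CSV_COLUMNS))
        df.insert(0, "time_min", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: KineticParameters | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(),
                   df[list(CSV_COLUMNS)].to_numpy(),
                   params if params is not None else KineticParameters(),
                   meta={"source": str(path)})


def integrate(
    initial: SystemState,
    params: KineticParameters,
    t_end: float,
    output_resolution: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval: np.ndarray | None = None,
    meta: dict | None = None,
) -> Trajectory:
    """Integrate the stiff circuit ODEs over ``[0, t_end]`` (LSODA).

    ``output_resolution`` sets the number of evenly spaced output points when
    ``t_eval`` is not given.  Raw solver output is clipped at zero only when
    packaged into states; tolerances are tight enough that this is a no-op in
    practice.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, int(output_resolution) + 1)
    sol = solve_ivp(
        _rhs_vec, (0.0, float(t_end)), initial.as_array(), args=(params,),
        method="LSODA", rtol=rtol, atol=atol, t_eval=np.asarray(t_eval, float),
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integrator failed at t = {t_fail:.6g} min: {sol.message}",
                               t_fail=t_fail)
    states = np.clip(sol.y.T, 0.0, None)
    m = dict(meta or {})
    m.setdefault("rtol", rtol)
    m.setdefault("atol", atol)
    return Trajectory(sol.t, states, params, m)


def steady_state(
    initial: SystemState,
    params: KineticParameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    tol: float = STEADY_STATE_TOL,
    t_cap: float = STEADY_STATE_CAP,
    chunk: float = 2e4,
) -> tuple[SystemState, float]:
    """Integrate until all molecular derivatives fall below ``tol`` nM/min.

    Returns the settled state and the integration time spent.  The density N
    is excluded from the criterion (it converges to the carrying capacity
    along with the molecular relaxation).  Raises :class:`IntegrationError`
    if the criterion is not met within ``t_cap`` minutes.
    """
    y = initial.as_array()
    t = 0.0
    while t < t_cap:
        span = min(chunk, t_cap - t)
        sol = solve_ivp(_rhs_vec, (0.0, span), y, args=(params,),
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed at t = {t + sol.t[-1]:.6g} min: {sol.message}",
                t_fail=t + float(sol.t[-1]))
        y = sol.y[:, -1]
        t += span
        deriv = np.abs(_rhs_vec(0.0, y, params))[_MOLECULAR]
        if deriv.max() < tol:
            return SystemState.from_array(y), t
    raise IntegrationError(
        f"no steady state within {t_cap:g} min "
        f"(max molecular |d/dt| = {deriv.max():.3g} nM/min)", t_fail=t_cap)
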