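"""Kinetic and analytical parameter sets for the LuxR-LuxI quorum-sensing circuit.

Two parameter containers live here:

* :class:`KineticParameters` — the full mass-action rate-constant set of the
  mechanistic ODE model (monomer/dimer binding, activated and basal expression,
  degradation, AHL synthesis and membrane exchange, logistic growth).
* :class:`AnalyticalParams` — the reduced closed-form memory theory's symbols
  (growth rate, total-LuxR decay rate, basal production rates, fold change,
  AHL synthesis rate, cell volume, activation threshold, post-dilution density).

Both validate on construction and can round-trip through YAML/JSON configs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, asdict, replace
from pathlib import Path

import yaml

__all__ = ["KineticParameters", "AnalyticalParams", "circuit_defaults", "analytical_defaults"]

_REL_TOL = 1e-9

# Fields that must be strictly positive (equilibrium constants, binding rates,
# geometry); the remaining rate constants may be zero (the binding-only and
# no-growth reductions used in conservation checks are legitimate inputs).
_STRICT_POS = {"k1", "k2", "k_m1", "k_m2", "kd1", "kd2", "kdI", "kdR", "r", "N_max"}
_NON_NEG = {"k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10", "k11", "b", "D"}


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the LuxR-LuxI circuit ODEs.

    Units: association rates k1, k2 in nM^-1 min^-1; dissociation rates k_m1,
    k_m2 in min^-1; dissociation constants kd1, kd2 and half-activation dimer
    levels kdI, kdR in nM; production rates k3-k6, k10 in nM min^-1;
    degradation/growth rates k7-k9, k11 and the AHL synthesis rate b and
    membrane diffusion rate D in min^-1; cell volume r in ml; carrying
    capacity N_max in cell/ml.
    """

    k_m1: float = 10.0      # monomer (RA) dissociation
    k_m2: float = 1.0       # dimer (C) dissociation
    kd1: float = 100.0      # monomer dissociation constant
    kd2: float = 20.0       # dimer dissociation constant
    k1: float = 0.1         # monomer formation, k_m1/kd1
    k2: float = 0.05        # dimer formation, k_m2/kd2
    b: float = 0.04         # AHL synthesis per LuxI
    D: float = 10.0         # AHL membrane diffusion
    k3: float = 80.0        # activated LuxI expression
    k4: float = 80.0        # activated LuxR expression
    k5: float = 8.0         # basal LuxI expression
    k6: float = 8.0         # basal LuxR expression
    kdI: float = 100.0      # dimer level at half-max LuxI promoter activity
    kdR: float = 100.0      # dimer level at half-max LuxR promoter activity
    k7: float = 0.006       # LuxI (and target gene) degradation
    k8: float = 0.15        # unbound-LuxR degradation
    k9: float = 0.005       # AHL degradation
    k11: float = 0.017      # growth rate (doubling time ~ 40 min)
    k10: float = 0.5        # basal target-gene expression
    r: float = 1e-12        # cell volume v_cell, ml
    N_max: float = 1e11     # carrying capacity, cell/ml
    # Model-structure switches. `monomer_degradation` restores the k8 term on
    # the signal-bound monomer RA; the default omits it, which is required for
    # the circuit to retain any phenotypic memory (see docs/methods.md).
    monomer_degradation: bool = False
    g_activated_by_k3: bool = False  # use k3 instead of k4 in the target-gene ODE

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in _STRICT_POS:
                if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                    raise ValueError(f"parameter {f.name} must be finite and > 0, got {v!r}")
            elif f.name in _NON_NEG:
                if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                    raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if self.r > 1e-9:
            raise ValueError(f"parameter r (cell volume) implausibly large: {self.r} ml")
        if self.N_max < 1.0:
            raise ValueError(f"parameter N_max must be >= 1 cell/ml, got {self.N_max}")
        for ka, km, kd in (("k1", "k_m1", "kd1"), ("k2", "k_m2", "kd2")):
            lhs = getattr(self, ka)
            rhs = getattr(self, km) / getattr(self, kd)
            if abs(lhs - rhs) > _REL_TOL * max(abs(lhs), abs(rhs)):
                raise ValueError(
                    f"inconsistent binding constants: {ka}={lhs} but "
                    f"{km}/{kd}={rhs}"
                )

    @classmethod
    def from_dissociation_constants(cls, **kw) -> "KineticParameters":
        """Build a set with k1, k2 derived from k_m1/kd1 and k_m2/kd2."""
        kw.pop("k1", None)
        kw.pop("k2", None)
        base = cls()
        k_m1 = kw.get("k_m1", base.k_m1)
        kd1 = kw.get("kd1", base.kd1)
        k_m2 = kw.get("k_m2", base.k_m2)
        kd2 = kw.get("kd2", base.kd2)
        return cls(k1=k_m1 / kd1, k2=k_m2 / kd2, **kw)

    def with_(self, **kw) -> "KineticParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kw)

    # -- config I/O ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "KineticParameters":
        """Read parameters from a YAML or JSON config keyed by symbol name."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @property
    def doubling_time(self) -> float:
        """Generation time ln2 / k11, min."""
        return math.log(2.0) / self.k11


def circuit_defaults(**overrides) -> KineticParameters:
    """The published rate-constant set of the V. fischeri-inspired circuit."""
    return KineticParameters(**overrides)


@dataclass(frozen=True)
class AnalyticalParams:
    """Parameters of the reduced closed-form memory theory.

    The reduced model tracks per-cell LuxI and total LuxR as single
    exponentials after dilution, accumulates extracellular AHL without
    degradation, and declares activation when the receptor-signal binding
    rate crosses ``R_OFF * A_thresh`` (rate constant fixed to 1).

    Primary fields are the basal production rates ``beta_I``/``beta_R``
    (nM/min); the OFF-state concentrations ``I_OFF = beta_I / gamma`` and
    ``R_OFF = beta_R / gamma_R`` are derived, so sweeps over the growth rate
    hold protein production fixed.
    """

    gamma: float = 0.017            # growth rate, 1/min
    gamma_intrinsic: float = 0.001  # intrinsic total-LuxR degradation, 1/min
    beta_I: float = 17.0            # basal LuxI production, nM/min
    beta_R: float = 18.0            # basal total-LuxR production, nM/min
    FC: float = 10.0                # ON/OFF fold change, shared by LuxI and LuxR
    b: float = 0.04                 # AHL synthesis per LuxI, 1/min
    v_cell: float = 1e-12           # cell volume, ml
    A_thresh: float = 20.0          # AHL concentration needed for activation, nM
    N_0: float = 1e8                # post-dilution cell density, cell/ml
    binding_constant: float = 1.0   # receptor-signal binding rate constant
    horizon: float = 700.0          # exponential-growth window, min

    def __post_init__(self) -> None:
        for name in ("gamma", "beta_I", "beta_R", "b", "v_cell", "A_thresh", "N_0",
                     "binding_constant", "horizon"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be finite and > 0, got {v!r}")
        if not (math.isfinite(self.gamma_intrinsic) and self.gamma_intrinsic >= 0):
            raise ValueError(f"gamma_intrinsic must be >= 0, got {self.gamma_intrinsic!r}")
        if self.FC < 1.0:
            raise ValueError(f"FC must be >= 1, got {self.FC!r}")

    @property
    def gamma_R(self) -> float:
        """Total-LuxR decay rate: dilution plus intrinsic degradation."""
        return self.gamma + self.gamma_intrinsic

    @property
    def I_OFF(self) -> float:
        return self.beta_I / self.gamma

    @property
    def R_OFF(self) -> float:
        return self.beta_R / self.gamma_R

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.gamma

    @classmethod
    def from_off_states(cls, I_OFF: float, R_OFF: float, **kw) -> "AnalyticalParams":
        """Build from OFF-state concentrations instead of production rates."""
        gamma = kw.get("gamma", cls.gamma)
        gamma_intrinsic = kw.get("gamma_intrinsic", cls.gamma_intrinsic)
        kw.pop("beta_I", None)
        kw.pop("beta_R", None)
        return cls(beta_I=I_OFF * gamma, beta_R=R_OFF * (gamma + gamma_intrinsic), **kw)

    def with_(self, **kw) -> "AnalyticalParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalyticalParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)


def analytical_defaults(**overrides) -> AnalyticalParams:
    """Reduced-theory parameter set of the published phase diagrams.

    gamma = 0.017/min (40-min doubling), gamma_R = 0.018/min, b = 0.04/min,
    I_OFF = 1000 nM, A_thresh = 20 nM, v_cell = 1e-12 ml, FC = 10,
    N_0 = 1e8 cell/ml, 700-min growth window.
    """
    return AnalyticalParams(**overrides)
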