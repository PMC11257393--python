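"""Synthetic inputs for exercising the pipeline end to end.

The deactivation time courses the decay fitter consumes are, in the study
itself, produced by the ODE model and are noiseless.  To test the fitter's
statistical behaviour we generate traces from the same single-exponential
model class with multiplicative log-normal noise (concentrations are
positive, and measurement error on fluorescence-like readouts scales with
the signal).  Perturbed kinetic-parameter sets support robustness sweeps,
and a fixture bundle collects the reference objects the test-suite shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import KineticParameters, analytical_defaults

__all__ = ["SyntheticDecayTrace", "gen_decay_trace", "gen_parameter_draws",
           "gen_reference_fixtures"]

DEFAULT_NOISE_SIGMA = 0.02


@dataclass(frozen=True)
class SyntheticDecayTrace:
    """A noisy exponential-decay time course with known ground truth."""

    C_on: float
    C_off: float
    gamma: float
    time: np.ndarray
    values: np.ndarray
    noise_sigma: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if (self.values <= 0).any():
            raise ValueError("synthetic observations must be strictly positive")

    def truth(self) -> tuple[float, float, float]:
        return self.C_on, self.C_off, self.gamma

    def ideal(self) -> np.ndarray:
        return self.C_on * np.exp(-self.gamma * self.time) + self.C_off


def gen_decay_trace(
    C_on: float,
    C_off: float,
    gamma: float,
    n_points: int = 200,
    t_max: float | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> SyntheticDecayTrace:
    """Evenly sampled noisy exponential ``C_on e^{-gamma t} + C_off``.

    Noise is multiplicative log-normal: each observation is the ideal curve
    times ``exp(sigma * z)``.  ``noise_sigma = 0`` returns the exact curve;
    the same seed always regenerates the identical trace.
    """
    if gamma <= 0:
        raise ValueError(f"decay rate must be > 0, got {gamma}")
    if n_points < 10:
        raise ValueError(f"need at least 10 points, got {n_points}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if t_max is None:
        t_max = 5.0 / gamma   # cover the decay down to <1% of the amplitude
    t = np.linspace(0.0, t_max, int(n_points))
    ideal = C_on * np.exp(-gamma * t) + C_off
    rng = np.random.default_rng(seed)
    noise = np.exp(noise_sigma * rng.standard_normal(t.size)) if noise_sigma > 0 else 1.0
    return SyntheticDecayTrace(C_on, C_off, gamma, t, ideal * noise,
                               noise_sigma, seed)


_PERTURBABLE = ("k_m1", "k_m2", "kd1", "kd2", "b", "D", "k3", "k4", "k5", "k6",
                "kdI", "kdR", "k7", "k8", "k9", "k10", "k11")


def gen_parameter_draws(
    base: KineticParameters,
    log_uniform_halfwidth: float = 0.1,
    n: int = 10,
    seed: int = 0,
) -> list[KineticParameters]:
    """Perturbed kinetic-parameter sets, log-uniform within ± halfwidth decades.

    Binding consistency (k1 = k_m1/kd1, k2 = k_m2/kd2) is preserved by
    re-deriving the association rates after perturbation.
    """
    if not 0 <= log_uniform_halfwidth < 1.0:
        raise ValueError("halfwidth must lie in [0, 1) decades")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(int(n)):
        kw = {}
        for name in _PERTURBABLE:
            factor = 10.0 ** rng.uniform(-log_uniform_halfwidth, log_uniform_halfwidth)
            kw[name] = getattr(base, name) * factor
        kw["r"] = base.r
        kw["N_max"] = base.N_max
        kw["monomer_degradation"] = base.monomer_degradation
        kw["g_activated_by_k3"] = base.g_activated_by_k3
        draws.append(KineticParameters.from_dissociation_constants(**kw))
    return draws


def gen_reference_fixtures(
    params: KineticParameters | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Build (and optionally persist) the shared reference bundle.

    Contents: the ON/OFF steady states, the standard memory-protocol scenario
    descriptions, the published analytical parameter set of the phase
    diagrams, and a deterministic noisy decay trace for the fitter.
    """
    from .scenarios import characterize_states

    params = params if params is not None else KineticParameters()
    ref = characterize_states(params)
    trace = gen_decay_trace(10.0, 1.0, 0.023, seed=seed)
    bundle = {
        "params": params,
        "reference": ref,
        "analytical": analytical_defaults(),
        "scenarios": {
            "growth_from_single_cell": {"initial": "OFF", "N_start": 1.0, "note": "growth from a single cell"},
            "memory": {"N_start": 10 ** 8.5, "grid": [8.7, 9.3, 10.0]},
            "over_dilution": {"N_start": 1e7},
        },
        "decay_trace": trace,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params.to_file(out / "params.yaml")
        states = {
            "ON": {k: getattr(ref.on, k) for k in
                   ("I", "R", "RA", "C", "A", "Aex", "G", "N")},
            "OFF": {k: getattr(ref.off, k) for k in
                    ("I", "R", "RA", "C", "A", "Aex", "G", "N")},
        }
        (out / "reference_states.json").write_text(json.dumps(states, indent=2))
        (out / "analytical_params.json").write_text(
            json.dumps(bundle["analytical"].to_dict(), indent=2))
        (out / "scenarios.json").write_text(json.dumps(bundle["scenarios"], indent=2))
        np.savetxt(out / "decay_trace.csv",
                   np.column_stack([trace.time, trace.values]),
                   delimiter=",", header="time_min,value", comments="",
                   fmt="%.12g")
    return bundle
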