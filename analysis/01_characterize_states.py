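"""Characterize the circuit's two phenotypes and its critical density.

Grows empty cells (all molecular species zero) from 1 cell/ml to saturation
at two carrying capacities — 1e11 cell/ml (activated, ON) and 1e7 cell/ml
(basal, OFF) — then locates the critical carrying capacity where the
steady-state target-gene level crosses half of the ON-OFF span, under two
protocols: growth from a single cell, and growth of an OFF-initialised
population from 10^8.5 cell/ml.

Writes results/characterization.json.
"""

import json
from pathlib import Path

import qsmemory as qs

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    params = qs.circuit_defaults()
    ref = qs.characterize_states(params)
    print("ON steady state  (N_max = 1e11):",
          {k: round(getattr(ref.on, k), 2) for k in qs.SPECIES})
    print("OFF steady state (N_max = 1e7): ",
          {k: round(getattr(ref.off, k), 3) for k in qs.SPECIES})
    fc = ref.fold_change
    print(f"LuxI fold change I_ON/I_OFF = {fc:.2f}")

    nc_single = qs.critical_density(params, ref, initial="OFF", N_start=1.0)
    nc_off = qs.critical_density(params, ref, initial="OFF", N_start=10 ** 8.5)
    nc_on = qs.critical_density(params, ref, initial="ON", N_start=10 ** 8.5)
    print(f"critical density, growth from 1 cell/ml: 10^{nc_single:.2f} cell/ml")
    print(f"critical density, OFF start at 10^8.5:  10^{nc_off:.2f}")
    print(f"critical density, ON start at 10^8.5:   10^{nc_on:.2f} "
          f"(hysteresis gap {nc_off - nc_on:.2f} decades)")

    out = {
        "fold_change_luxI": fc,
        "on_state": {k: getattr(ref.on, k) for k in qs.SPECIES},
        "off_state": {k: getattr(ref.off, k) for k in qs.SPECIES},
        "log10_Nc_from_single_cell": nc_single,
        "log10_Nc_off_start_1e8.5": nc_off,
        "log10_Nc_on_start_1e8.5": nc_on,
    }
    (OUT / "characterization.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {OUT / 'characterization.json'}")


if __name__ == "__main__":
    main()
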