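"""Map the memory zone and show that over-dilution destroys it.

Populations taken from the ON and OFF steady states are diluted to a common
starting density and grown to a range of carrying capacities.  Near the
critical density the final activity state depends on the initial one — the
memory zone.  Starting from 10^8.5 cell/ml the zone is wide and contains
10^9.3; starting from 10^7 cell/ml (over-dilution) the carried biomolecules
decay before reactivation can exploit them and the zone closes.

Writes results/activation_curves_{8.5,7.0}.csv and results/memory_zones.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import qsmemory as qs

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def sweep(params, ref, n_start, label):
    grid = np.linspace(8.5, 10.5, 41)
    c_on, c_off = qs.activation_curves(params, ref, N_start=n_start, grid=grid)
    zone = qs.memory_zone((c_on, c_off), params, ref)
    pd.DataFrame({
        "log10_Nmax": grid,
        "final_G_norm_on_start": c_on.final_g_norm,
        "final_G_norm_off_start": c_off.final_g_norm,
        "state_on_start": c_on.labels,
        "state_off_start": c_off.labels,
    }).to_csv(OUT / f"activation_curves_{label}.csv", index=False)
    return zone


def main() -> None:
    params = qs.circuit_defaults()
    ref = qs.characterize_states(params)

    zone = sweep(params, ref, 10 ** 8.5, "8.5")
    print(f"N_start = 10^8.5: memory zone 10^{zone.lower:.2f} .. 10^{zone.upper:.2f} "
          f"cell/ml (width {zone.width_log10:.2f} decades), "
          f"contains 10^9.3: {zone.contains(9.3)}")
    for log_n in (8.7, 9.3, 10.0):
        st_on = qs.run_to_steady(params, "ON", 10 ** 8.5, 10 ** log_n, ref)
        st_off = qs.run_to_steady(params, "OFF", 10 ** 8.5, 10 ** log_n, ref)
        print(f"  N_max = 10^{log_n}: ON-start -> "
              f"{qs.classify_activity(st_on, ref)}, OFF-start -> "
              f"{qs.classify_activity(st_off, ref)}")

    zone_od = sweep(params, ref, 1e7, "7.0")
    print(f"N_start = 10^7 (over-dilution): width {zone_od.width_log10:.2f} decades "
          f"(empty: {zone_od.is_empty})")

    (OUT / "memory_zones.json").write_text(json.dumps({
        "N_start_1e8.5": {"lower_log10": zone.lower, "upper_log10": zone.upper,
                          "width_log10": zone.width_log10},
        "N_start_1e7": {"lower_log10": zone_od.lower, "upper_log10": zone_od.upper,
                        "width_log10": zone_od.width_log10},
    }, indent=2))
    print(f"wrote {OUT / 'memory_zones.json'}")


if __name__ == "__main__":
    main()
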