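#!/usr/bin/env python
"""Steady-state action potentials of normal and infarcted mid-myocardial cells.

Paces each cell model 100 beats at a cycle length of 1000 ms, writes the final
AP traces and reports resting potential and APD90.  The infarcted cell carries
the ionic remodeling (I_Na 38%, I_CaL 31%, I_Kr 30%, I_Ks 20% of normal).

Writes results/single_cell/ap_normal_m.csv, ap_infarct_m.csv, summary.csv.
"""

import pathlib

import pandas as pd

from fibrovw import ionic

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "single_cell"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, remodeled in [("normal_m", False), ("infarct_m", True)]:
        params = ionic.make_cell_params("M", remodeled=remodeled)
        res = ionic.pace_single_cell(params, bcl=1000.0, n_beats=100)
        ionic.write_ap_trace(OUT / f"ap_{name}.csv", res.time, res.vm)
        rows.append(dict(cell=name, rest_mv=res.vm[0], peak_mv=res.vm.max(),
                         apd90_ms=res.apd90, excited=res.excited))
        print(f"{name}: rest {res.vm[0]:.1f} mV, peak {res.vm.max():.1f} mV, "
              f"APD90 {res.apd90:.1f} ms")
    pd.DataFrame(rows).to_csv(OUT / "summary.csv", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
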