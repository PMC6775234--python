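#!/usr/bin/env python
"""Ring-strip surrogates of measured scars, plus the synthetic-scar emulator.

Two arc-infarct geometries stand in for the measured ventricular scars:
length/width/distance of 25/60/10 % (a wide transmural band) and 25/35/10 %
(a thin band).  The thin band is expected to show a 0 ms vulnerable window
with or without fibrosis; the wide band with 20% fibrosis sustains reentry in
the full 210 mm domain (S1-S2 window 520-560 ms).  Desk-scale defaults cannot
reproduce that window (docs/methods.md); pass --scale 1 --step 5 for the
full-domain run (hours on one CPU).

Also generates a seeded synthetic ventricular-slice scar, writes its mask as a
PNG and its four-layer gradient partition sizes.

Writes results/scar_surrogate/.
"""

import argparse
import pathlib

from fibrovw import experiments, geometry as geo

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "scar_surrogate"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scale", type=float, default=0.2)
    ap.add_argument("--step", type=float, default=40.0)
    ap.add_argument("--seeds", type=int, nargs="+", default=[0, 1, 2])
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    tables = []
    for ln, wd, ds, fibs in [(25.0, 60.0, 10.0, (0, 20)),
                             (25.0, 35.0, 10.0, (0, 20))]:
        df = experiments.exp_scar_surrogate(ln, wd, ds, fibrosis=fibs,
                                            seeds=args.seeds, scale=args.scale,
                                            step=args.step, max_interval=560.0)
        tables.append(df)
    import pandas as pd
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT / "table.csv", index=False)
    agg = experiments.summarize(table, by=["length", "width", "distance", "fibrosis"])
    print(agg.to_string(index=False))
    experiments.report(table, by=["width", "fibrosis"], out_dir=OUT,
                       name="scar_surrogate")

    # synthetic-slice emulator: irregular scar + 4-layer gradient partition
    grid, scar, layers = geo.generate_synthetic_scar(seed=args.seeds[0])
    grid.to_image(OUT / "synthetic_scar_mask.png")
    spec = geo.GradientSpec(geo.SCAR_GRADIENT_PROFILE,
                            weights=[len(l) for l in layers])
    fib = geo.apply_gradient_fibrosis(grid, layers, spec, seed=args.seeds[0])
    fib.to_image(OUT / "synthetic_scar_gradient_fibrosis.png")
    print(f"synthetic scar: {scar.size} nodes, layer sizes "
          f"{[len(l) for l in layers]}, gradient mean {spec.mean_percent:.1f}%")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
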