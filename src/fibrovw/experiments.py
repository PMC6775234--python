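"""Scripted reproductions of the four in-silico studies, at configurable scale.

Each experiment turns a geometric/fibrosis specification into tissue masks,
runs the S1-S2 vulnerable-window scan per seed, and emits a tidy table (one
row per seed x condition) mirroring the bar-chart data model of the studies:
fibrosis distribution (random vs gradient) in square tissue, and infarct
length / width / position sweeps plus the scar-surrogate comparison in ring
tissue.

The ``scale`` factor shrinks grid sizes and pixel radii proportionally while
keeping dx fixed: conduction velocity and wavelength are unchanged but path
lengths shrink, so absolute VW values are scale-dependent and only full-scale
runs (scale=1) target the printed full-domain results.  See docs/methods.md
for what the reduced scale preserves.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from . import geometry as geo
from .ionic import make_cell_params, pace_single_cell
from .protocols import aggregate_seeds, endocardial_block, left_edge_band, scan_vw
from .solver import SolverConfig

# full-scale study dimensions
SQUARE_GRID_N = 1000
SQUARE_DX = 0.25            # mm
SQUARE_RADII = (70, 140, 210, 280, 350)   # infarct layer circles, nodes
RING_GRID_N = 600
RING_DX = 0.35              # mm
FIBROSIS_LEVELS = (6, 11, 16, 23, 26, 28, 31)   # percent, distribution study
SCAN_START = 480.0          # ms
SCAN_STEP_FINE = 1.0        # ms, distribution study
SCAN_STEP_COARSE = 5.0      # ms, ring studies
N_SEEDS = 6                 # 11 for the infarct-length sweep
N_SEEDS_LENGTH = 11


@lru_cache(maxsize=None)
def steady_state(subtype: str = "M", remodeled: bool = False, n_beats: int = 100):
    """Pre-paced single-cell state (bcl 1000 ms) used as tissue initial condition."""
    params = make_cell_params(subtype, remodeled=remodeled)
    return pace_single_cell(params, bcl=1000.0, n_beats=n_beats).final_state


def tissue_init_states(n_beats: int = 100) -> dict:
    """Initial-condition map for mid-myocardial tissue (normal + infarct)."""
    return {("M", False): steady_state("M", False, n_beats),
            ("M", True): steady_state("M", True, n_beats)}


def _scaled(x, scale):
    return max(1, int(round(x * scale)))


def _scan_kwargs(kw):
    out = dict(start=SCAN_START, step=SCAN_STEP_COARSE, max_interval=600.0)
    out.update(kw)
    return out


def _row(condition: dict, res) -> dict:
    row = dict(condition)
    row.update(vw_lower=res.vw_lower, vw_upper=res.vw_upper, vw_width=res.width,
               n_reentry=res.n_reentry,
               conduction_lower_bound=res.conduction_lower_bound)
    return row


def exp_distribution(levels=FIBROSIS_LEVELS, distributions=("random", "gradient"),
                     seeds=range(N_SEEDS), scale: float = 1.0,
                     init_states=None, prepace_beats: int = 100,
                     **scan_kw) -> pd.DataFrame:
    """Random vs gradient fibrosis in square tissue with a circular infarct.

    For each fibrosis level, the gradient condition rescales the 35/30/25/20/15
    five-ring profile so its area-weighted mean matches the level of the random
    condition.  Returns one row per (level, distribution, seed).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    grid_n = _scaled(SQUARE_GRID_N, scale)
    radii = [_scaled(r, scale) for r in SQUARE_RADII]
    base, layers = geo.build_square_with_circular_infarct(grid_n, SQUARE_DX, radii)
    region = np.concatenate(layers)
    if init_states is None:
        init_states = tissue_init_states(prepace_beats)
    kw = _scan_kwargs(dict(step=SCAN_STEP_FINE) | scan_kw)
    cfg = SolverConfig(duration=float(kw["max_interval"]) + 900.0)
    rows = []
    for level in levels:
        grad = geo.match_gradient_to_mean(level)
        for dist in distributions:
            for seed in seeds:
                if dist == "random":
                    g = geo.sprinkle_random_fibrosis(base, region, level, seed)
                elif dist == "gradient":
                    g = geo.apply_gradient_fibrosis(base, layers, grad, seed)
                else:
                    raise ValueError(f"unknown distribution {dist!r}")
                res = scan_vw(g, cfg, left_edge_band(g), seed=seed,
                              init_states=init_states, **kw)
                rows.append(_row(dict(experiment="distribution", level=level,
                                      distribution=dist, seed=seed, scale=scale),
                                 res))
    return pd.DataFrame(rows)


def _ring_grid(length_pct, width_pct, distance_pct, fibrosis_pct, seed, scale):
    spec = geo.RingSpec(grid_n=_scaled(RING_GRID_N, scale),
                        length_frac=length_pct / 100.0,
                        width_frac=width_pct / 100.0,
                        distance_frac=distance_pct / 100.0)
    g, infarct = geo.build_ring(spec, RING_DX)
    if fibrosis_pct and infarct.size:
        g = geo.sprinkle_random_fibrosis(g, infarct, fibrosis_pct, seed)
    return g


def exp_ring_sweep(varied: str, values, fixed: dict | None = None,
                   fibrosis=(0, 20), seeds=None, scale: float = 1.0,
                   init_states=None, prepace_beats: int = 100,
                   **scan_kw) -> pd.DataFrame:
    """Sweep infarct length, width or position (percent) in the ring tissue.

    ``fixed`` overrides the non-varied geometry percentages (defaults: length
    25, width 50, distance 0, as in the studies).  One row per
    (value, fibrosis, seed).
    """
    if varied not in ("length", "width", "position"):
        raise ValueError("varied must be 'length', 'width' or 'position'")
    if seeds is None:
        seeds = range(N_SEEDS_LENGTH if varied == "length" else N_SEEDS)
    geom = dict(length=25.0, width=50.0, distance=0.0)
    geom.update(fixed or {})
    if init_states is None:
        init_states = tissue_init_states(prepace_beats)
    kw = _scan_kwargs(scan_kw)
    cfg = SolverConfig(duration=float(kw["max_interval"]) + 900.0)
    key = {"length": "length", "width": "width", "position": "distance"}[varied]
    rows = []
    for value in values:
        if not 0 <= value <= 100:
            raise ValueError("sweep values are percentages in [0, 100]")
        gm = dict(geom)
        gm[key] = float(value)
        for fib in fibrosis:
            for seed in seeds:
                g = _ring_grid(gm["length"], gm["width"], gm["distance"],
                               fib, seed, scale)
                res = scan_vw(g, cfg, endocardial_block(g), seed=seed,
                              init_states=init_states, **kw)
                rows.append(_row(dict(experiment=f"ring_{varied}", varied=varied,
                                      value=float(value), fibrosis=fib,
                                      seed=seed, scale=scale, **{
                                          f"geom_{k}": v for k, v in gm.items()}),
                                 res))
    return pd.DataFrame(rows)


def exp_scar_surrogate(length_pct: float = 25.0, width_pct: float = 60.0,
                       distance_pct: float = 10.0, fibrosis=(0, 20),
                       seeds=range(N_SEEDS), scale: float = 1.0,
                       init_states=None, prepace_beats: int = 100,
                       **scan_kw) -> pd.DataFrame:
    """Ideal ring-strip surrogate of a measured scar (length/width/distance %)."""
    if init_states is None:
        init_states = tissue_init_states(prepace_beats)
    kw = _scan_kwargs(scan_kw)
    cfg = SolverConfig(duration=float(kw["max_interval"]) + 900.0)
    rows = []
    for fib in fibrosis:
        for seed in seeds:
            g = _ring_grid(length_pct, width_pct, distance_pct, fib, seed, scale)
            res = scan_vw(g, cfg, endocardial_block(g), seed=seed,
                          init_states=init_states, **kw)
            rows.append(_row(dict(experiment="scar_surrogate",
                                  length=length_pct, width=width_pct,
                                  distance=distance_pct, fibrosis=fib,
                                  seed=seed, scale=scale), res))
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, by) -> pd.DataFrame:
    """Mean +/- SD of VW width over seeds per condition (bar-chart aggregate)."""
    if table.empty:
        return pd.DataFrame(columns=list(by) + ["vw_mean", "vw_sd", "n"])
    out = []
    for keys, sub in table.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        w = sub["vw_width"].to_numpy(dtype=float)
        out.append(dict(zip(by, keys))
                   | dict(vw_mean=float(w.mean()),
                          vw_sd=float(w.std(ddof=1)) if w.size > 1 else 0.0,
                          n=int(w.size)))
    return pd.DataFrame(out)


def report(table: pd.DataFrame, by, out_dir, name: str = "experiment") -> str:
    """Write a bar chart (mean +/- SD per condition) and a markdown summary.

    Returns the path of the markdown report.
    """
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = summarize(table, by)
    md = out_dir / f"{name}.md"
    lines = [f"# {name}", ""]
    if agg.empty:
        lines.append("No conditions to report.")
    else:
        fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(agg), 3.2))
        labels = [" / ".join(str(k) for k in row) for row in agg[list(by)].itertuples(index=False)]
        ax.bar(range(len(agg)), agg["vw_mean"], yerr=agg["vw_sd"], capsize=3,
               color="#b03030")
        ax.set_xticks(range(len(agg)), labels, rotation=45, ha="right")
        ax.set_ylabel("VW width (ms)")
        fig.tight_layout()
        fig.savefig(out_dir / f"{name}.png", dpi=120)
        plt.close(fig)
        lines.append("```\n" + agg.to_string(index=False) + "\n```")
        lines.append("")
        lines.append(f"![bars]({name}.png)")
    md.write_text("\n".join(lines) + "\n")
    return str(md)
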