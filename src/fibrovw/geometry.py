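"""Tissue-geometry builders: 2D label masks for all simulation domains.

Label semantics (zero-sided fibroblast coupling): VOID nodes are outside the
tissue, NORMAL and INFARCT nodes carry TP06 membrane state (INFARCT with the
remodeled parameter set), FIBROTIC nodes are unexcitable, non-conducting 1x1
obstacles with no electrical coupling to their neighbours.

Generators are pure functions of (spec, seed): repeated calls give
byte-identical masks.  Fibrosis is realized as exact-count sampling without
replacement, so a "p% fibrosis" region contains exactly round(p/100 * size)
fibrotic nodes and seed-to-seed variance reflects placement only.

Rasterization: a node belongs to an ideal region iff its center lies inside it
(center-in test); indexing is 0-based row-major with (0,0) top-left; angles are
measured counterclockwise from the +x (rightward) direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage


class Label(IntEnum):
    VOID = 0
    NORMAL = 1
    INFARCT = 2
    FIBROTIC = 3


# 8-bit grayscale encoding used for PNG/PGM mask files
GRAY_OF_LABEL = {Label.VOID: 0, Label.NORMAL: 85, Label.INFARCT: 170, Label.FIBROTIC: 255}
LABEL_OF_GRAY = {v: k for k, v in GRAY_OF_LABEL.items()}


@dataclass
class TissueGrid:
    """A 2D simulation domain: label mask plus isotropic node spacing dx (mm)."""

    labels: np.ndarray          # int8, shape (ny, nx)
    dx: float                   # mm per node

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def physical_size_mm(self) -> tuple[float, float]:
        """Domain extent (height, width) in mm."""
        return (self.shape[0] * self.dx, self.shape[1] * self.dx)

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == label))

    def indices_of(self, label: Label) -> np.ndarray:
        """Flat (row-major) indices of all nodes with the given label."""
        return np.flatnonzero(self.labels.ravel() == label)

    def copy(self) -> "TissueGrid":
        return TissueGrid(self.labels.copy(), self.dx)

    # ---- image round-trip ----
    def to_image(self, path) -> None:
        import imageio.v3 as iio
        gray = np.zeros(self.shape, dtype=np.uint8)
        for lab, g in GRAY_OF_LABEL.items():
            gray[self.labels == lab] = g
        iio.imwrite(path, gray)

    @classmethod
    def from_image(cls, path, dx: float) -> "TissueGrid":
        import imageio.v3 as iio
        gray = np.asarray(iio.imread(path))
        if gray.ndim == 3:
            gray = gray[..., 0]
        labels = np.zeros(gray.shape, dtype=np.int8)
        for g, lab in LABEL_OF_GRAY.items():
            labels[gray == g] = lab
        return cls(labels, dx)


@dataclass
class GradientSpec:
    """Concentric-layer fibrosis profile, ordered inside -> outside.

    ``percents[k]`` is the fibrosis percentage of layer k; ``weights`` are the
    relative layer areas used for the area-weighted mean (for L equal-width
    annuli of a disk these are the odd numbers 1, 3, 5, ...).
    """

    percents: tuple
    weights: tuple = None

    def __post_init__(self):
        self.percents = tuple(float(p) for p in self.percents)
        if any(not 0.0 <= p <= 100.0 for p in self.percents):
            raise ValueError("layer percentages must lie in [0, 100]")
        if self.weights is None:
            self.weights = tuple(2 * k + 1 for k in range(len(self.percents)))
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != len(self.percents):
            raise ValueError("weights and percents must have equal length")

    @property
    def mean_percent(self) -> float:
        """Area-weighted mean fibrosis percentage over all layers."""
        return float(np.dot(self.percents, self.weights) / sum(self.weights))


#: the five-ring gradient profile of the square-tissue study (inside -> outside)
DEFAULT_GRADIENT_PROFILE = (35.0, 30.0, 25.0, 20.0, 15.0)
#: the four-layer profile used for ventricular-slice scars
SCAR_GRADIENT_PROFILE = (35.0, 25.0, 15.0, 5.0)


def match_gradient_to_mean(target_mean_percent: float,
                           profile=DEFAULT_GRADIENT_PROFILE,
                           weights=None) -> GradientSpec:
    """Rescale a layer profile so its area-weighted mean equals the target.

    Layer ratios are preserved (every layer is multiplied by the same factor).
    Raises if the target is outside [0, 100] or if the rescaled innermost layer
    would exceed 100%.
    """
    if not 0.0 <= target_mean_percent <= 100.0:
        raise ValueError("target mean must lie in [0, 100]")
    base = GradientSpec(profile, weights)
    if base.mean_percent == 0.0:
        if target_mean_percent == 0.0:
            return base
        raise ValueError("cannot rescale an all-zero profile to a nonzero mean")
    scale = target_mean_percent / base.mean_percent
    percents = tuple(p * scale for p in base.percents)
    if max(percents) > 100.0 + 1e-9:
        raise ValueError(
            f"target mean {target_mean_percent}% infeasible: layer would need "
            f"{max(percents):.1f}% fibrosis")
    return GradientSpec(tuple(min(p, 100.0) for p in percents), base.weights)


def _disk_layers(shape, center, radii):
    """Flat-index node sets of the annuli between consecutive radii (in nodes)."""
    ny, nx = shape
    ii, jj = np.ogrid[:ny, :nx]
    r2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2
    layers = []
    prev = 0.0
    for r in radii:
        sel = (r2 <= r * r) & (r2 > prev * prev)
        layers.append(np.flatnonzero(sel.ravel()))
        prev = r
    return layers


def build_square_with_circular_infarct(grid_n: int, dx: float, circle_radii):
    """Square tissue with a central circular infarct split into concentric layers.

    ``circle_radii`` (strictly increasing, in nodes) bound the gradient layers;
    every node inside the outermost circle is INFARCT, the rest NORMAL.  Returns
    the grid and the per-layer flat-index sets (inside -> outside).
    """
    radii = list(circle_radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("circle radii must be strictly increasing")
    c = (grid_n - 1) / 2.0
    if radii[-1] > c + 0.5:
        raise ValueError(f"outermost circle radius {radii[-1]} exceeds grid of {grid_n} nodes")
    labels = np.full((grid_n, grid_n), Label.NORMAL, dtype=np.int8)
    layers = _disk_layers((grid_n, grid_n), (c, c), radii)
    flat = labels.ravel()
    for lay in layers:
        flat[lay] = Label.INFARCT
    return TissueGrid(labels, dx), layers


def sprinkle_random_fibrosis(grid: TissueGrid, region: np.ndarray, percent: float,
                             seed) -> TissueGrid:
    """Replace exactly round(percent/100 * |region|) region nodes by FIBROTIC ones.

    ``region`` is a flat-index node set; nodes are drawn uniformly without
    replacement under the given seed (or an existing numpy Generator).  The
    input grid is not modified.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ValueError("region is empty")
    flat = grid.labels.ravel()
    if np.any(flat[region] == Label.VOID):
        raise ValueError("region contains VOID nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(math.floor(percent / 100.0 * region.size + 0.5))
    out = grid.copy()
    if k:
        chosen = rng.choice(region.size, size=k, replace=False)
        out.labels.ravel()[region[chosen]] = Label.FIBROTIC
    return out


def apply_gradient_fibrosis(grid: TissueGrid, layers, spec: GradientSpec,
                            seed) -> TissueGrid:
    """Sprinkle fibrosis layer by layer at the percentages of a GradientSpec."""
    if len(layers) != len(spec.percents):
        raise ValueError("layer count does not match gradient profile length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = grid
    for lay, p in zip(layers, spec.percents):
        out = sprinkle_random_fibrosis(out, lay, p, rng)
    return out


@dataclass
class RingSpec:
    """Circular-ring tissue with an arc-shaped infarct.

    The infarct is parameterized by three dimensionless fractions:
    ``length_frac``  = infarct arc length / ring circumference,
    ``width_frac``   = infarct radial width / wall thickness,
    ``distance_frac``= radial gap between the inner wall and the infarct /
    wall thickness.  The wall is the annulus between ``inner_radius_mm`` and
    ``outer_radius_mm``; unset radii default to outer = 0.45 x domain side and
    inner = 0.5 x outer (the wall dimensions are an assumption of this package;
    see docs/methods.md).
    """

    grid_n: int = 600
    length_frac: float = 0.25
    width_frac: float = 0.5
    distance_frac: float = 0.0
    outer_radius_mm: float = None
    inner_radius_mm: float = None
    center_angle: float = 0.0       # radians, infarct angular center

    def resolve(self, dx: float) -> tuple[float, float]:
        r_out = self.outer_radius_mm if self.outer_radius_mm is not None \
            else 0.45 * self.grid_n * dx
        r_in = self.inner_radius_mm if self.inner_radius_mm is not None \
            else 0.5 * r_out
        return r_in, r_out

    def validate(self, dx: float) -> None:
        for name in ("length_frac", "width_frac", "distance_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.width_frac + self.distance_frac > 1.0 + 1e-9:
            raise ValueError("width_frac + distance_frac must not exceed 1 "
                             "(infarct must lie within the wall)")
        r_in, r_out = self.resolve(dx)
        if r_out <= r_in:
            raise ValueError("degenerate wall: outer radius must exceed inner radius")
        if r_out > self.grid_n * dx / 2.0:
            raise ValueError("outer radius exceeds the grid")


def build_ring(spec: RingSpec, dx: float = 0.35):
    """Rasterize a RingSpec: annular NORMAL wall, arc-shaped INFARCT, VOID elsewhere.

    Returns the grid and the infarct flat-index set.  With ``center_angle=0``
    the mask is mirror-symmetric about the horizontal axis through the center.
    """
    spec.validate(dx)
    n = spec.grid_n
    r_in, r_out = spec.resolve(dx)
    wall = r_out - r_in
    c = (n - 1) / 2.0
    ii, jj = np.ogrid[:n, :n]
    yy = -(ii - c) * dx     # +y upward so angles are counterclockwise
    xx = (jj - c) * dx
    rr = np.hypot(xx, yy)
    in_wall = (rr >= r_in) & (rr <= r_out)
    labels = np.where(in_wall, Label.NORMAL, Label.VOID).astype(np.int8)

    inf_lo = r_in + spec.distance_frac * wall
    inf_hi = inf_lo + spec.width_frac * wall
    half_ang = spec.length_frac * math.pi
    dang = np.arctan2(yy, xx) - spec.center_angle
    dang = np.abs((dang + math.pi) % (2.0 * math.pi) - math.pi)
    infarct = (in_wall & (rr >= inf_lo) & (rr <= inf_hi) & (dang <= half_ang)
               & (spec.length_frac > 0) & (spec.width_frac > 0))
    labels[infarct] = Label.INFARCT
    return TissueGrid(labels, dx), np.flatnonzero(infarct.ravel())


def generate_synthetic_scar(shape=(128, 128), dx: float = 0.35, seed=0,
                            scar_frac_bounds=(0.05, 0.35), n_layers: int = 4,
                            smooth_sigma: float = None, max_tries: int = 20):
    """Seeded generator of a ventricular-slice-like wall with an irregular scar.

    Emulates a short-axis slice: an annular wall (same default proportions as
    RingSpec) holding a single connected, irregularly shaped transmural scar
    obtained by thresholding a smoothed random field seeded by a radial bump at
    a random angle.  The scar is split into ``n_layers`` onion layers by
    distance from the scar centroid, for gradient fibrosis.  Deterministic per
    seed.  Returns (grid, scar_indices, layers).
    """
    ny, nx = shape
    if ny < 64 or nx < 64:
        raise ValueError("shape must be at least 64x64 nodes")
    rng = np.random.default_rng(seed)
    n = min(ny, nx)
    r_out = 0.45 * n * dx
    r_in = 0.5 * r_out
    c = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    ii, jj = np.ogrid[:ny, :nx]
    yy = -(ii - c[0]) * dx
    xx = (jj - c[1]) * dx
    rr = np.hypot(xx, yy)
    in_wall = (rr >= r_in) & (rr <= r_out)
    wall_area = int(np.count_nonzero(in_wall))
    if smooth_sigma is None:
        smooth_sigma = n / 16.0

    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r_mid = 0.5 * (r_in + r_out)
        bx, by = r_mid * math.cos(theta), r_mid * math.sin(theta)
        bump = np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2.0 * (r_out - r_in) ** 2))
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
        noise /= max(np.abs(noise).max(), 1e-12)
        fld = bump + 0.6 * noise
        target = rng.uniform(*scar_frac_bounds) * wall_area
        vals = fld[in_wall]
        thr = np.quantile(vals, 1.0 - target / wall_area)
        cand = in_wall & (fld >= thr)
        lab, nlab = ndimage.label(cand)
        if nlab == 0:
            continue
        bi, bj = int(round(c[0] - by / dx)), int(round(c[1] + bx / dx))
        comp = lab[bi, bj]
        if comp == 0:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, nlab + 1))
            comp = 1 + int(np.argmax(sizes))
        scar = lab == comp
        frac = scar.sum() / wall_area
        if scar_frac_bounds[0] * 0.5 <= frac <= scar_frac_bounds[1] * 1.5:
            break
    else:
        raise RuntimeError(f"no admissible scar after {max_tries} attempts")

    labels = np.where(in_wall, Label.NORMAL, Label.VOID).astype(np.int8)
    labels[scar] = Label.INFARCT
    scar_idx = np.flatnonzero(scar.ravel())

    # onion layers: distance from scar centroid, equal-width bins
    si, sj = np.nonzero(scar)
    ci, cj = si.mean(), sj.mean()
    d = np.hypot(si - ci, sj - cj)
    edges = np.linspace(0.0, d.max() + 1e-9, n_layers + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_layers - 1)
    layers = [scar_idx[which == k] for k in range(n_layers)]
    return TissueGrid(labels, dx), scar_idx, layers


def assign_transmural_subtypes(grid: TissueGrid, ratios=(25, 35, 40)) -> np.ndarray:
    """Bin wall nodes by normalized transmural depth into ENDO / M / EPI bands.

    ``ratios`` (endo:M:epi, summing to 100) set the band widths from the inner
    (endocardial) to the outer (epicardial) surface.  Depth is computed from
    Euclidean distances to the inner cavity and to the outside, so the
    operation works for any closed wall, not only ideal rings.  Returns an int8
    map with 0=ENDO, 1=M, 2=EPI on wall nodes and -1 elsewhere.
    """
    if abs(sum(ratios) - 100) > 1e-9:
        raise ValueError("ratios must sum to 100")
    wall = grid.labels != Label.VOID
    if wall.all():
        raise ValueError("open geometry: no VOID region, transmural depth undefined")
    void_lab, n_void = ndimage.label(~wall)
    border = np.zeros_like(wall)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside_ids = set(np.unique(void_lab[border & ~wall])) - {0}
    inner = (~wall) & ~np.isin(void_lab, sorted(outside_ids))
    if not inner.any():
        raise ValueError("open geometry: wall has no enclosed cavity")
    d_in = ndimage.distance_transform_edt(~inner)
    d_out = ndimage.distance_transform_edt(np.isin(void_lab, sorted(outside_ids),
                                                   invert=True))
    depth = np.where(wall, d_in / np.maximum(d_in + d_out, 1e-12), np.nan)
    cuts = np.cumsum(ratios)[:2] / 100.0
    sub = np.full(grid.shape, -1, dtype=np.int8)
    sub[wall] = 2
    sub[wall & (depth < cuts[1])] = 1
    sub[wall & (depth < cuts[0])] = 0
    return sub
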