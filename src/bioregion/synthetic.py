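"""Synthetic landscapes and floras with known ground truth.

The landscape generator plants K spatially contiguous environmental
regimes (Voronoi cells of seeded points, optionally smoothed random
fields), gives every base variable a regime-specific mean plus spatially
smoothed Gaussian noise, appends deliberately collinear variable blocks
(linear combinations of base variables plus small noise, to exercise VIF
pruning), and masks a nodata border.  The flora generator assigns every
taxon a home unit and draws presences as independent Bernoulli flags with
probability ``p_home`` at home and ``p_background`` elsewhere.  All
randomness descends from one root seed via named substreams, so any stage
can be regenerated independently.

Regime mean vectors default to binary contrast patterns (greedy max–min
Hamming selection) scaled to ``separation_sd`` within-regime standard
deviations, which keeps any two regimes separated by the stated amount in
at least a handful of variables regardless of the seed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import ClusterMap, RasterGrid, RasterStack, write_cluster_map, write_raster

__all__ = [
    "CollinearBlock",
    "LandscapeSpec",
    "FloraSpec",
    "GroundTruth",
    "simulate_landscape",
    "simulate_flora",
    "make_fixture_suite",
]

_DEFAULT_FAMILIES = {
    "Asteraceae": 0.19,
    "Fabaceae": 0.11,
    "Lamiaceae": 0.09,
    "Caryophyllaceae": 0.07,
    "Brassicaceae": 0.06,
    "Poaceae": 0.05,
    "Apiaceae": 0.05,
    "Amaranthaceae": 0.04,
    "Plumbaginaceae": 0.03,
    "Ranunculaceae": 0.03,
    "Other": 0.28,
}


@dataclass
class CollinearBlock:
    """A derived variable: linear combination of base variables + noise."""

    name: str
    sources: list[str]
    coefficients: list[float]
    noise_sd_fraction: float = 0.05  # relative to the combination's sd


@dataclass
class LandscapeSpec:
    rows: int = 60
    cols: int = 60
    k_true: int = 5
    n_base_vars: int = 6
    regime_means: np.ndarray | None = None  # k_true × n_base_vars, else generated
    separation_sd: float = 3.0
    within_sd: float = 1.0
    smoothing_length: float = 2.0
    geometry: str = "voronoi"  # or "smoothed_fields"
    collinear_blocks: list[CollinearBlock] = field(default_factory=list)
    nodata_border_fraction: float = 0.05
    geotransform: tuple[float, float, float, float] = (-10.0, 38.0, 0.01, -0.01)
    crs_label: str = "EPSG:4326"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.regime_means is not None:
            m = np.asarray(self.regime_means, dtype=float)
            if m.shape != (self.k_true, self.n_base_vars):
                raise ValueError("regime_means must be k_true × n_base_vars")
            self.regime_means = m


def default_collinear_blocks(n_blocks: int = 2, base_codes: list[str] | None = None) -> list[CollinearBlock]:
    """Standard two-source blocks over the first base variables."""
    codes = base_codes or [f"env{j + 1}" for j in range(2 * n_blocks)]
    blocks = []
    for b in range(n_blocks):
        s1, s2 = codes[(2 * b) % len(codes)], codes[(2 * b + 1) % len(codes)]
        blocks.append(CollinearBlock(name=f"coll{b + 1}", sources=[s1, s2], coefficients=[1.0, 0.5]))
    return blocks


@dataclass
class FloraSpec:
    n_taxa: int = 300
    p_home: float = 0.9
    p_background: float = 0.05
    family_weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FAMILIES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_background <= 1 and 0 <= self.p_home <= 1):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    cluster_map: ClusterMap | None = None
    regime_means: np.ndarray | None = None
    variable_codes: list[str] = field(default_factory=list)
    collinear_blocks: list[CollinearBlock] = field(default_factory=list)
    home_units: dict[str, str] = field(default_factory=dict)  # taxon -> unit


def _substream(seed: int, name: str) -> np.random.Generator:
    # crc32 keeps the substream key deterministic across processes
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return np.random.default_rng(ss)


def _contrast_patterns(k: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """K binary rows of length p with greedily maximized min Hamming distance."""
    candidates = rng.integers(0, 2, size=(max(256, 8 * k), p))
    chosen = [np.zeros(p, dtype=int)]
    while len(chosen) < k:
        dists = np.stack([(candidates != c).sum(axis=1) for c in chosen]).min(axis=0)
        chosen.append(candidates[int(dists.argmax())].copy())
    return np.array(chosen, dtype=float)


def _regime_map(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    if spec.geometry == "voronoi":
        # Best-candidate (farthest-point) seed placement keeps Voronoi cells
        # comparably sized, so every planted regime is substantively present.
        pool = np.column_stack([rng.uniform(0, spec.rows, 64), rng.uniform(0, spec.cols, 64)])
        seeds = [pool[0]]
        while len(seeds) < spec.k_true:
            dmin = np.min([((pool - s) ** 2).sum(axis=1) for s in seeds], axis=0)
            seeds.append(pool[int(dmin.argmax())])
        seeds = np.array(seeds)
        d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
        return d2.argmin(axis=2) + 1
    if spec.geometry == "smoothed_fields":
        fields = ndimage.gaussian_filter(
            rng.standard_normal((spec.k_true, spec.rows, spec.cols)), sigma=(0, spec.rows / 6, spec.cols / 6)
        )
        return fields.argmax(axis=0) + 1
    raise ValueError(f"unknown regime geometry {spec.geometry!r}")


def _smoothed_noise(rng: np.random.Generator, shape, sd: float, length: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if length <= 0:
        return sd * white
    smooth = ndimage.gaussian_filter(white, sigma=length)
    s = smooth.std()
    return sd * (smooth / s if s > 0 else smooth)


def simulate_landscape(spec: LandscapeSpec) -> tuple[RasterStack, GroundTruth]:
    """Generate an aligned raster stack with a known regime map.

    Base variable v = regime_mean[k, v] + smoothed Gaussian noise; each
    collinear block's derived variable is the stated linear combination of
    base variables plus noise scaled to ``noise_sd_fraction`` of the
    combination's spread.  Bit-identical for equal seeds.
    """
    rng_geom = _substream(spec.seed, "geometry")
    rng_noise = _substream(spec.seed, "noise")
    rng_means = _substream(spec.seed, "means")

    regime = _regime_map(spec, rng_geom)
    means = spec.regime_means
    if means is None:
        patterns = _contrast_patterns(spec.k_true, spec.n_base_vars, rng_means)
        means = spec.separation_sd * spec.within_sd * patterns

    border = int(round(spec.nodata_border_fraction * min(spec.rows, spec.cols)))
    mask = np.zeros((spec.rows, spec.cols), dtype=bool)
    if border > 0:
        mask[:border, :] = mask[-border:, :] = True
        mask[:, :border] = mask[:, -border:] = True

    base_codes = [f"env{j + 1}" for j in range(spec.n_base_vars)]
    layers: list[tuple[str, RasterGrid]] = []
    base_values: dict[str, np.ndarray] = {}
    for j, code in enumerate(base_codes):
        values = means[regime - 1, j] + _smoothed_noise(
            rng_noise, (spec.rows, spec.cols), spec.within_sd, spec.smoothing_length
        )
        base_values[code] = values
        layers.append((code, RasterGrid(values, mask.copy(), spec.geotransform, spec.crs_label)))

    for block in spec.collinear_blocks:
        combo = np.zeros((spec.rows, spec.cols))
        for src, coef in zip(block.sources, block.coefficients):
            combo += coef * base_values[src]
        noise_sd = block.noise_sd_fraction * max(combo.std(), 1e-12)
        values = combo + rng_noise.standard_normal(combo.shape) * noise_sd
        layers.append((block.name, RasterGrid(values, mask.copy(), spec.geotransform, spec.crs_label)))

    labels = np.where(mask, 0, regime).astype(np.int32)
    truth = GroundTruth(
        cluster_map=ClusterMap(labels=labels, K=spec.k_true, geotransform=spec.geotransform, crs_label=spec.crs_label),
        regime_means=means,
        variable_codes=[c for c, _ in layers],
        collinear_blocks=list(spec.collinear_blocks),
    )
    return RasterStack(layers), truth


def simulate_flora(
    spec: FloraSpec, units: list[str], classes: dict[str, str] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a checklist with probabilistic affinity to a home unit.

    Taxon i is present in its home unit with probability ``p_home`` and in
    every other unit independently with ``p_background``; home units cycle
    through ``units`` so classes stay balanced.  When a unit→class map is
    given the home is a whole class instead: the taxon is present with
    ``p_home`` in every unit of its home class, planting class-level
    indicator taxa.  Returns the checklist as a DataFrame in the standard
    schema plus the planted truth.
    """
    if not units:
        raise ValueError("need at least one analysis unit")
    rng = _substream(spec.seed, "flora")
    families = list(spec.family_weights)
    weights = np.array([spec.family_weights[f] for f in families], dtype=float)
    weights /= weights.sum()

    if classes is not None:
        class_names = sorted(set(classes.values()))
        home_pool = class_names
        home_of = lambda u, home: classes[u] == home  # noqa: E731
    else:
        home_pool = units
        home_of = lambda u, home: u == home  # noqa: E731

    records = []
    homes: dict[str, str] = {}
    for i in range(spec.n_taxa):
        home = home_pool[i % len(home_pool)]
        name = f"Taxon aff{i + 1:04d}"
        family = families[rng.choice(len(families), p=weights)]
        flags = {}
        for u in units:
            p = spec.p_home if home_of(u, home) else spec.p_background
            flags[f"unit:{u}"] = int(rng.random() < p)
        records.append({"taxon": name, "family": family, "genus": name.split()[0], "rank": "species", **flags})
        homes[name] = home
    df = pd.DataFrame(records)
    return df, GroundTruth(home_units=homes)


def make_fixture_suite(out_dir: str, scale: str = "tiny", seed: int = 0) -> dict[str, str]:
    """Write a complete worked dataset (stack + manifest + checklist + truth).

    ``tiny`` is a 60×60 grid with 6 base + 2 collinear variables and
    K_true = 5; ``standard`` is 200×200 with 29 base + 4 collinear
    variables (33 total) and K_true = 11.  Returns the paths written.
    """
    if scale == "tiny":
        lspec = LandscapeSpec(
            rows=60, cols=60, k_true=5, n_base_vars=6,
            collinear_blocks=default_collinear_blocks(2), seed=seed,
        )
        fspec = FloraSpec(n_taxa=300, p_home=0.9, p_background=0.05, seed=seed)
    elif scale == "standard":
        lspec = LandscapeSpec(
            rows=200, cols=200, k_true=11, n_base_vars=29,
            collinear_blocks=default_collinear_blocks(4), seed=seed,
        )
        fspec = FloraSpec(n_taxa=1600, p_home=0.9, p_background=0.05, seed=seed)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    os.makedirs(out_dir, exist_ok=True)
    stack, truth = simulate_landscape(lspec)
    manifest_rows = []
    for code, grid in stack.layers:
        fname = f"{code}.tif"
        write_raster(grid, os.path.join(out_dir, fname))
        manifest_rows.append({"variable_code": code, "path": fname})
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)

    units = [str(k) for k in range(1, lspec.k_true + 1)]
    checklist, ftruth = simulate_flora(fspec, units)
    checklist_path = os.path.join(out_dir, "checklist.csv")
    checklist.to_csv(checklist_path, index=False)

    truth_tif = os.path.join(out_dir, "truth_clusters.tif")
    write_cluster_map(truth.cluster_map, truth_tif)
    sidecar = {
        "k_true": lspec.k_true,
        "variable_codes": truth.variable_codes,
        "collinear_blocks": [
            {"name": b.name, "sources": b.sources, "coefficients": b.coefficients} for b in lspec.collinear_blocks
        ],
        "regime_means": np.asarray(truth.regime_means).tolist(),
        "home_units": ftruth.home_units,
        "seed": seed,
        "scale": scale,
    }
    truth_json = os.path.join(out_dir, "truth.json")
    with open(truth_json, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return {
        "manifest": manifest_path,
        "checklist": checklist_path,
        "truth_map": truth_tif,
        "truth_json": truth_json,
    }
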