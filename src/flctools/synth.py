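"""Synthetic-data generators with known ground truth for every pipeline.

These generators stand in for the study's raw image stacks and deposited
per-cell tables (synthetic data only; no microscopy realism such as PSF
anisotropy or spectral bleed-through is attempted). Each generator is a
pure function of its spec and seed: identical inputs give bit-identical
outputs.

Defaults encode the study conditions: 1000 simulated cell files of 30
cells, observation at days 7/15/21, ~72% / 1.5% of cells without
appreciable expression in the intermediate / null-repressor genotypes, ON
cell mRNA means in a ~1:5 ratio, qPCR decay half-lives of 5 h (mRNA) and
1.5 h (protein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sim import (
    CellCycleModel,
    EmissionParams,
    SimulationConfig,
    SwitchingParams,
    simulate_root,
)
from .fish import MarkerSet
from .venus import SegmentedRoot

__all__ = [
    "SynthImageSpec",
    "SynthTableSpec",
    "FishStackTruth",
    "make_fish_stack",
    "make_venus_volume",
    "make_cell_table",
    "make_qpcr_decay",
    "make_count_table",
    "make_venus_trend_table",
    "make_qpcr_timeseries",
    "COUNT_TABLE_DEFAULTS",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class SynthImageSpec:
    """Geometry and signal levels for synthetic 3-D stacks."""

    shape: tuple[int, int, int] = (9, 64, 64)
    n_cells: int = 4
    spots_per_cell: int = 5
    spot_amplitude: float = 10.0
    spot_sigma: float = 1.0
    nuclear_amplitude: float = 5.0
    nuclear_radius: int = 6
    background: float = 1.0
    noise_sd: float = 0.0
    min_separation: float = 6.0
    boundary_margin: float = 3.0  # spots stay this much deeper in their own cell
    occluded: tuple[int, ...] = ()  # 0-based cell indices flagged occluded
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.shape) < (5, 32, 32):
            raise ValueError("shape must be at least (5, 32, 32)")
        for a in (self.spot_amplitude, self.nuclear_amplitude, self.background):
            if a < 0:
                raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class SynthTableSpec:
    """Simulator parameters behind a synthetic per-cell intensity table."""

    switching: SwitchingParams
    emission: EmissionParams
    config: SimulationConfig
    genotype: str = "fca-3"


@dataclass
class FishStackTruth:
    probe: np.ndarray
    dapi: np.ndarray
    spots: pd.DataFrame  # true continuous (z, y, x) positions and cell ids
    markers: MarkerSet
    labels: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _add_gaussian_blob(vol: np.ndarray, center: np.ndarray, amplitude: float, sigma: float) -> None:
    r = max(int(np.ceil(3 * sigma)), 1)
    lo = np.maximum(np.floor(center).astype(int) - r, 0)
    hi = np.minimum(np.floor(center).astype(int) + r + 1, vol.shape)
    grids = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    vol[tuple(slice(a, b) for a, b in zip(lo, hi))] += amplitude * np.exp(-d2 / (2 * sigma**2))


def make_fish_stack(spec: SynthImageSpec) -> FishStackTruth:
    """Synthetic smFISH stack: nearest-seed cell regions, nuclear blobs on the
    DAPI channel, Gaussian spots at recorded positions on the probe channel.

    Spots avoid the top and bottom z-slices and respect ``min_separation``
    where geometrically possible; otherwise a warning is recorded in the
    truth metadata.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    # seeds on a jittered y-x grid at mid depth
    g = int(np.ceil(np.sqrt(spec.n_cells)))
    ys = np.linspace(ny / (2 * g), ny - ny / (2 * g), g)
    xs = np.linspace(nx / (2 * g), nx - nx / (2 * g), g)
    centers = np.array([(nz // 2, y, x) for y in ys for x in xs])[: spec.n_cells]
    centers[:, 1:] += rng.uniform(-2, 2, size=(spec.n_cells, 2))
    centers = np.clip(np.round(centers).astype(int), 0, np.array(spec.shape) - 1)

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
    voxels = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    _, nearest = cKDTree(centers).query(voxels)
    labels = (nearest + 1).reshape(spec.shape).astype(np.int32)

    probe = np.full(spec.shape, spec.background, dtype=float)
    dapi = np.full(spec.shape, spec.background, dtype=float)
    for c in centers:
        _add_gaussian_blob(dapi, c.astype(float), spec.nuclear_amplitude, spec.nuclear_radius / 2.0)

    notes: list[str] = []
    spot_rows = []
    placed: list[np.ndarray] = []
    spot_id = 1
    dists = cKDTree(centers).query(voxels, k=min(2, spec.n_cells))[0]
    if spec.n_cells > 1:
        interior = dists[:, 1] - dists[:, 0] >= spec.boundary_margin
    else:
        interior = np.ones(len(voxels), dtype=bool)
    for cell_idx in range(spec.n_cells):
        eligible = (
            (labels.ravel() == cell_idx + 1)
            & (voxels[:, 0] >= 1)
            & (voxels[:, 0] <= nz - 2)
            & interior
        )
        cell_voxels = voxels[eligible]
        if not len(cell_voxels):  # tiny cells: fall back to any in-cell voxel
            cell_voxels = voxels[
                (labels.ravel() == cell_idx + 1) & (voxels[:, 0] >= 1) & (voxels[:, 0] <= nz - 2)
            ]
        for _ in range(spec.spots_per_cell):
            pos = None
            for _attempt in range(50):
                cand = cell_voxels[rng.integers(len(cell_voxels))].astype(float)
                cand += rng.uniform(-0.3, 0.3, 3)
                cand[0] = np.clip(cand[0], 1.0, nz - 2.0)
                if all(np.linalg.norm(cand - p) >= spec.min_separation for p in placed):
                    pos = cand
                    break
            if pos is None:
                pos = cand
                notes.append(
                    f"cell {cell_idx + 1}: spot placed below the requested minimum separation"
                )
            placed.append(pos)
            _add_gaussian_blob(probe, pos, spec.spot_amplitude, spec.spot_sigma)
            spot_rows.append(
                {"spot_id": spot_id, "cell_id": cell_idx + 1, "z": pos[0], "y": pos[1], "x": pos[2]}
            )
            spot_id += 1
    if spec.noise_sd > 0:
        probe = probe + rng.normal(0, spec.noise_sd, spec.shape)
        dapi = dapi + rng.normal(0, spec.noise_sd, spec.shape)
    visible = np.array([i not in spec.occluded for i in range(spec.n_cells)])
    markers = MarkerSet(coords=centers, visible=visible)
    spots = pd.DataFrame(spot_rows, columns=["spot_id", "cell_id", "z", "y", "x"])
    return FishStackTruth(probe=probe, dapi=dapi, spots=spots, markers=markers, labels=labels, warnings=notes)


def make_venus_volume(spec: SynthImageSpec) -> tuple[SegmentedRoot, pd.DataFrame]:
    """Labeled slab cells, each with one bright near-uniform nuclear ball.

    The nuclear ball sits at the slab center with intensity
    ``background + contrast * (1 + 0.01 * (1 - d^2/r^2))``: flat to within
    1% but strictly peaked at the center so the intensity arg-max is the
    true nucleus center. The truth table records (cell_id, contrast) and
    flags cells whose nominal ball does not fit the cell extent.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    venus = np.full(spec.shape, spec.background, dtype=float)
    edges = np.linspace(0, nx, spec.n_cells + 1).astype(int)
    rows = []
    zz, yy, xxg = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
    for cell_id in range(1, spec.n_cells + 1):
        x0, x1 = edges[cell_id - 1], edges[cell_id]
        labels[:, :, x0:x1] = cell_id
        center = np.array([nz // 2, ny // 2, (x0 + x1) // 2])
        r = spec.nuclear_radius
        fits = (
            center[0] - r >= 0 and center[0] + r < nz
            and center[1] - r >= 0 and center[1] + r < ny
            and center[2] - r >= x0 and center[2] + r < x1
        )
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xxg - center[2]) ** 2
        inside = d2 <= r**2
        contrast = spec.nuclear_amplitude
        venus[inside] += contrast * (1.0 + 0.01 * (1.0 - d2[inside] / max(r**2, 1)))
        rows.append({"cell_id": cell_id, "contrast": contrast, "ball_fits": bool(fits)})
    if spec.noise_sd > 0:
        venus = venus + rng.normal(0, spec.noise_sd, spec.shape)
    truth = pd.DataFrame(rows)
    return SegmentedRoot(labels=labels, venus=venus), truth


def make_cell_table(spec: SynthTableSpec) -> tuple[pd.DataFrame, dict]:
    """Per-cell Venus intensity table in the deposited-table shape.

    Runs the simulator and writes one row per cell and output time with
    columns (genotype, time_d, file_id, position, n_active_copies,
    intensity). The sidecar dict records the generating parameters.
    """
    res = simulate_root(spec.config, spec.switching, spec.emission)
    df = res.to_dataframe()
    df.insert(0, "genotype", spec.genotype)
    df["time_d"] = df["time_h"] / HOURS_PER_DAY
    sidecar = {
        "genotype": spec.genotype,
        "p_off": spec.switching.p_off,
        "p_on": spec.switching.p_on,
        "mu_on": spec.emission.mu_on,
        "sigma_on": spec.emission.sigma_on,
        "mu_off": spec.emission.mu_off,
        "sigma_off": spec.emission.sigma_off,
        "seed": spec.config.seed,
        "n_files": spec.config.n_files,
        "file_length": spec.config.file_length,
    }
    return df[
        ["genotype", "time_d", "file_id", "position", "n_active_copies", "intensity"]
    ], sidecar


def make_qpcr_decay(
    half_life_h: float,
    times_h=(0.0, 1.5, 3.0, 6.0, 12.0, 24.0),
    noise_cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    genotype: str = "fca-1",
    target: str = "FLC",
) -> pd.DataFrame:
    """Exponential-decay qPCR series with multiplicative log-normal noise.

    ``noise_cv`` is the coefficient of variation of the unit-mean noise
    factor; housekeeping channels are constant. Columns: sample_id,
    genotype, target, time_h, abundance, pp2a, ubc.
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    rng = np.random.default_rng(seed)
    times_h = np.asarray(times_h, dtype=float)
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for rep in range(n_reps):
        decay = np.exp(-np.log(2.0) * times_h / half_life_h)
        if noise_cv > 0:
            decay = decay * rng.lognormal(-(sigma**2) / 2, sigma, times_h.size)
        for t, lvl in zip(times_h, decay):
            rows.append(
                {
                    "sample_id": f"{genotype}_rep{rep}_t{t:g}",
                    "genotype": genotype,
                    "target": target,
                    "time_h": t,
                    "abundance": lvl,
                    "pp2a": 1.0,
                    "ubc": 1.0,
                }
            )
    return pd.DataFrame(rows)


# Per-genotype smFISH count conditions. ``off_fraction`` is the probability
# that a cell shows no appreciable expression (<= 3 mRNAs); ``on_mean`` the
# negative-binomial mean of expressing cells (dispersion r=2, a typical
# smFISH burstiness level); the intermediate:null ON-mean ratio is ~1:5.
COUNT_TABLE_DEFAULTS = {
    "fca-3": {"n_cells": 1088, "off_fraction": 0.72, "on_mean": 8.0},
    "fca-1": {"n_cells": 792, "off_fraction": 0.015, "on_mean": 40.0},
    "Ler": {"n_cells": 853, "off_fraction": 0.95, "on_mean": 6.0},
}
_NB_DISPERSION = 2.0


def _nb_conditional(rng: np.random.Generator, mean: float, size: int, above: int) -> np.ndarray:
    """Negative-binomial draws conditioned on being strictly above ``above``."""
    r = _NB_DISPERSION
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size)
    bad = out <= above
    while np.any(bad):
        out[bad] = rng.negative_binomial(r, p, int(bad.sum()))
        bad = out <= above
    return out


def make_count_table(
    genotype: str = "fca-3",
    n_cells: int | None = None,
    off_fraction: float | None = None,
    on_mean: float | None = None,
    on_threshold: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell mRNA count table emulating the deposited smFISH quantification.

    A cell is OFF with probability ``off_fraction`` and then draws a count
    in {0..on_threshold} (truncated Poisson background); otherwise it draws
    a negative-binomial count conditioned above the threshold. The measured
    fraction of cells at or below the threshold is therefore the stated
    ``off_fraction`` in expectation. Columns: genotype, cell_id, count.
    """
    defaults = COUNT_TABLE_DEFAULTS.get(genotype, COUNT_TABLE_DEFAULTS["fca-3"])
    n_cells = defaults["n_cells"] if n_cells is None else n_cells
    off_fraction = defaults["off_fraction"] if off_fraction is None else off_fraction
    on_mean = defaults["on_mean"] if on_mean is None else on_mean
    rng = np.random.default_rng(seed)
    is_off = rng.random(n_cells) < off_fraction
    counts = np.empty(n_cells, dtype=int)
    n_off = int(is_off.sum())
    if n_off:
        bg = rng.poisson(0.8, n_off)
        while np.any(bg > on_threshold):
            m = bg > on_threshold
            bg[m] = rng.poisson(0.8, int(m.sum()))
        counts[is_off] = bg
    if n_cells - n_off:
        counts[~is_off] = _nb_conditional(rng, on_mean, n_cells - n_off, on_threshold)
    return pd.DataFrame(
        {"genotype": genotype, "cell_id": np.arange(1, n_cells + 1), "count": counts}
    )


def make_venus_trend_table(
    slope_per_d: float = -0.0077,
    intercept: float = 0.45,
    times_d=(7.0, 15.0, 21.0),
    n_cells_per_t=(2875, 3553, 3663),
    noise_sd: float = 0.5,
    seed: int = 0,
    genotype: str = "fca-3",
) -> pd.DataFrame:
    """Per-cell Venus intensities with a small linear population trend.

    Defaults encode the intermediate genotype's observed per-cell decline of
    -0.0077 intensity units per day across the three observation days, with
    cell counts matching the study's pooled roots. Columns: genotype,
    time_d, intensity.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t, n in zip(times_d, n_cells_per_t):
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "time_d": float(t),
                    "intensity": intercept + slope_per_d * t + rng.normal(0, noise_sd, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_qpcr_timeseries(
    slope_per_d: float = -0.13,
    intercept: float = 3.1,
    times_d=(7.0, 15.0, 21.0),
    n_reps: int = 3,
    noise_sd: float = 0.08,
    seed: int = 0,
    genotype: str = "fca-3",
) -> pd.DataFrame:
    """Housekeeping-normalized expression timeseries with a linear trend.

    Defaults encode the intermediate genotype's observed decline of
    -0.13 relative units per day over days 7-21. Columns: genotype,
    time_d, replicate, rel_expr.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in times_d:
        for rep in range(n_reps):
            rows.append(
                {
                    "genotype": genotype,
                    "time_d": float(t),
                    "replicate": rep,
                    "rel_expr": intercept + slope_per_d * t + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
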