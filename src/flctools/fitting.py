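"""Reproducible fitting of switching and emission parameters to Venus histograms.

The observed data are per-cell Venus intensity distributions at a few
timepoints (days 7, 15, 21 in the study design). The simulator is run at
candidate parameters, censused intensities are binned on shared edges, and
the objective is the summed total-variation (TV) distance between model and
data histograms across timepoints. Common random numbers (a fixed seed per
objective evaluation) make the stochastic objective a deterministic function
of the parameters.

The search is a coarse log-grid over (p_off, p_on) with moment-initialized
emission parameters, followed by alternating Nelder-Mead refinement of the
switching and emission blocks. Because cell states depend only on the
switching probabilities, emission refinement reuses cached state censuses
and is cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .sim import (
    CellCycleModel,
    EmissionParams,
    SimulationConfig,
    SwitchingParams,
    census,
    simulate_root,
)

__all__ = [
    "FitDataset",
    "FitResult",
    "default_bins",
    "histogram_objective",
    "moment_init_emission",
    "fit_parameters",
]

HOURS_PER_DAY = 24.0


@dataclass
class FitDataset:
    """Per-timepoint vectors of per-cell Venus intensities, keyed by day."""

    intensities: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.intensities) < 2:
            raise ValueError("need at least two timepoints to constrain switching dynamics")
        self.intensities = {
            float(d): np.asarray(v, dtype=float) for d, v in self.intensities.items()
        }
        for d, v in self.intensities.items():
            if v.size == 0:
                raise ValueError(f"empty intensity vector at day {d}")

    @property
    def days(self) -> list[float]:
        return sorted(self.intensities)

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.intensities[d] for d in self.days])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genotype: str | None = None) -> "FitDataset":
        if genotype is not None:
            df = df[df["genotype"] == genotype]
        return cls({d: g["intensity"].to_numpy() for d, g in df.groupby("time_d")})


@dataclass
class FitResult:
    switching: SwitchingParams
    emission: EmissionParams
    objective: float
    trace: pd.DataFrame
    seed: int


def default_bins(data: FitDataset, n_bins: int = 40, lo_pct: float = 0.1, hi_pct: float = 99.9) -> np.ndarray:
    """Shared bin edges spanning the pooled data's central percentile range."""
    pooled = data.pooled()
    lo, hi = np.percentile(pooled, [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _bin_fractions(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Normalized histogram with the outermost bins extended to +/- infinity."""
    if x.size == 0:
        raise ValueError("cannot histogram an empty vector")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1).astype(float)
    return counts / counts.sum()


def histogram_objective(
    model_intensities: dict[float, np.ndarray],
    data: FitDataset,
    bins: np.ndarray,
) -> float:
    """Summed total-variation distance between model and data histograms.

    Zero iff the binned distributions are identical at every timepoint; each
    timepoint contributes at most 1 (disjoint supports).
    """
    total = 0.0
    for d in data.days:
        p = _bin_fractions(np.asarray(model_intensities[d], dtype=float), bins)
        q = _bin_fractions(data.intensities[d], bins)
        total += 0.5 * np.abs(p - q).sum()
    return float(total)


def moment_init_emission(data7: np.ndarray, on_threshold: float = 1.0) -> EmissionParams:
    """Initialize emission parameters from log-moments of the earliest timepoint.

    Sub-threshold cells estimate the background (mu_off, sigma_off);
    super-threshold cells, after subtracting the median background and
    halving (two active copies dominate early on), estimate the signal.
    Falls back to global moments with a warning if either group is empty.
    """
    data7 = np.asarray(data7, dtype=float)
    sub = data7[data7 <= on_threshold]
    sup = data7[data7 > on_threshold]
    tiny = 1e-9
    if sub.size == 0 or sup.size == 0:
        warnings.warn(
            "one intensity group empty at the ON threshold; "
            "falling back to global log-moments",
            stacklevel=2,
        )
        logs = np.log(np.clip(data7, tiny, None))
        m, s = float(logs.mean()), float(logs.std())
        return EmissionParams(mu_on=m, sigma_on=s, mu_off=m, sigma_off=s)
    log_bg = np.log(np.clip(sub, tiny, None))
    bg_median = float(np.median(sub))
    log_sig = np.log(np.clip((sup - bg_median) / 2.0, tiny, None))
    return EmissionParams(
        mu_on=float(log_sig.mean()),
        sigma_on=float(log_sig.std()),
        mu_off=float(log_bg.mean()),
        sigma_off=float(log_bg.std()),
    )


def _apply_emission(
    states_by_day: dict[float, np.ndarray],
    normals: dict[float, tuple[np.ndarray, np.ndarray]],
    em: EmissionParams,
) -> dict[float, np.ndarray]:
    """Map censused state vectors to intensities using frozen standard normals."""
    out = {}
    for d, k in states_by_day.items():
        z_on, z_off = normals[d]
        out[d] = k * np.exp(em.mu_on + em.sigma_on * z_on) + np.exp(em.mu_off + em.sigma_off * z_off)
    return out


def _simulate_states(
    sw: SwitchingParams,
    config: SimulationConfig,
    cyc: CellCycleModel,
    days: list[float],
) -> dict[float, np.ndarray]:
    cfg = SimulationConfig(
        n_files=config.n_files,
        file_length=config.file_length,
        timestep=config.timestep,
        duration=max(d * HOURS_PER_DAY for d in days),
        output_times=tuple(d * HOURS_PER_DAY for d in days),
        exclude_bottom=config.exclude_bottom,
        seed=config.seed,
    )
    res = simulate_root(cfg, sw, em=None, cyc=cyc)
    out = {}
    for d in days:
        s = res.states[d * HOURS_PER_DAY][:, cfg.exclude_bottom :]
        out[d] = s.ravel().astype(float)
    return out


def fit_parameters(
    data: FitDataset,
    config: SimulationConfig,
    p_off_bounds: tuple[float, float] = (1e-4, 0.1),
    p_on_bounds: tuple[float, float] = (1e-5, 0.05),
    n_grid: tuple[int, int] = (9, 5),
    bins: np.ndarray | None = None,
    on_threshold: float = 1.0,
    cyc: CellCycleModel | None = None,
    n_files_search: int = 300,
    n_files_final: int = 1000,
    seed: int = 0,
    maxiter: int = 60,
) -> FitResult:
    """Fit (p_off, p_on) and emission parameters to observed Venus histograms.

    Deterministic given ``seed``: simulations during the search use common
    random numbers, so each (parameters -> objective) evaluation is
    reproducible. The winning parameters are re-scored at ``n_files_final``
    files.
    """
    cyc = cyc or CellCycleModel()
    days = data.days
    edges = default_bins(data) if bins is None else np.asarray(bins, dtype=float)
    em0 = moment_init_emission(data.intensities[days[0]], on_threshold)

    trace_rows: list[dict] = []
    crn_rng = np.random.default_rng(np.random.SeedSequence([seed, 12345]).generate_state(1)[0])
    # frozen standard normals for emission, sized to the search census
    n_cells = n_files_search * (config.file_length - config.exclude_bottom)
    normals = {d: (crn_rng.standard_normal(n_cells), crn_rng.standard_normal(n_cells)) for d in days}
    n_cells_final = n_files_final * (config.file_length - config.exclude_bottom)
    normals_final = {
        d: (crn_rng.standard_normal(n_cells_final), crn_rng.standard_normal(n_cells_final))
        for d in days
    }

    search_cfg = SimulationConfig(
        n_files=n_files_search,
        file_length=config.file_length,
        timestep=config.timestep,
        duration=config.duration,
        output_times=config.output_times,
        exclude_bottom=config.exclude_bottom,
        seed=seed,
    )

    state_cache: dict[tuple[float, float], dict[float, np.ndarray]] = {}

    def states_for(p_off: float, p_on: float) -> dict[float, np.ndarray]:
        key = (round(float(p_off), 12), round(float(p_on), 12))
        if key not in state_cache:
            state_cache[key] = _simulate_states(
                SwitchingParams(*key), search_cfg, cyc, days
            )
        return state_cache[key]

    def objective(p_off: float, p_on: float, em: EmissionParams, stage: str) -> float:
        val = histogram_objective(_apply_emission(states_for(p_off, p_on), normals, em), data, edges)
        trace_rows.append(
            {
                "stage": stage,
                "p_off": p_off,
                "p_on": p_on,
                "mu_on": em.mu_on,
                "sigma_on": em.sigma_on,
                "mu_off": em.mu_off,
                "sigma_off": em.sigma_off,
                "objective": val,
                "warning": "",
            }
        )
        return val

    # --- coarse log-grid over the switching probabilities
    grid_off = np.geomspace(*p_off_bounds, n_grid[0])
    grid_on = np.geomspace(*p_on_bounds, n_grid[1])
    best = None
    for po in grid_off:
        for pn in grid_on:
            val = objective(po, pn, em0, "grid")
            if best is None or val < best[0]:
                best = (val, po, pn)
    _, p_off, p_on = best

    def clip_log(x: float, bounds: tuple[float, float], name: str) -> float:
        if x < bounds[0] or x > bounds[1]:
            trace_rows.append(
                {"stage": "clip", "p_off": p_off, "p_on": p_on, "mu_on": np.nan,
                 "sigma_on": np.nan, "mu_off": np.nan, "sigma_off": np.nan,
                 "objective": np.nan, "warning": f"{name} clipped to bounds"}
            )
        return float(np.clip(x, *bounds))

    def refine_em(em_start: EmissionParams) -> EmissionParams:
        # cheap: states for the current (p_off, p_on) are cached, only the
        # frozen-normal emission mapping is re-evaluated
        res = minimize(
            lambda v: objective(
                p_off, p_on,
                EmissionParams(mu_on=v[0], sigma_on=abs(v[1]), mu_off=v[2], sigma_off=abs(v[3])),
                "refine_em",
            ),
            x0=[em_start.mu_on, em_start.sigma_on, em_start.mu_off, em_start.sigma_off],
            method="Nelder-Mead",
            options={"maxfev": maxiter, "fatol": 1e-4},
        )
        return EmissionParams(
            mu_on=float(res.x[0]), sigma_on=abs(float(res.x[1])),
            mu_off=float(res.x[2]), sigma_off=abs(float(res.x[3])),
        )

    # --- refine emission at the grid winner, then switching, then emission
    em = refine_em(em0)
    res_sw = minimize(
        lambda v: objective(
            clip_log(10 ** v[0], p_off_bounds, "p_off"),
            clip_log(10 ** v[1], p_on_bounds, "p_on"),
            em,
            "refine_sw",
        ),
        x0=[np.log10(p_off), np.log10(p_on)],
        method="Nelder-Mead",
        options={"maxfev": maxiter, "xatol": 0.02, "fatol": 1e-4},
    )
    p_off = clip_log(10 ** res_sw.x[0], p_off_bounds, "p_off")
    p_on = clip_log(10 ** res_sw.x[1], p_on_bounds, "p_on")
    em = refine_em(em)

    # --- re-score the winner at full size
    final_states = _simulate_states(
        SwitchingParams(p_off, p_on),
        SimulationConfig(
            n_files=n_files_final, file_length=config.file_length,
            timestep=config.timestep, duration=config.duration,
            output_times=config.output_times, exclude_bottom=config.exclude_bottom,
            seed=seed,
        ),
        cyc, days,
    )
    final_obj = histogram_objective(_apply_emission(final_states, normals_final, em), data, edges)
    trace_rows.append(
        {"stage": "final", "p_off": p_off, "p_on": p_on, "mu_on": em.mu_on,
         "sigma_on": em.sigma_on, "mu_off": em.mu_off, "sigma_off": em.sigma_off,
         "objective": final_obj, "warning": ""}
    )
    return FitResult(
        switching=SwitchingParams(p_off, p_on),
        emission=em,
        objective=final_obj,
        trace=pd.DataFrame(trace_rows),
        seed=seed,
    )
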