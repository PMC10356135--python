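"""Stochastic simulation of digital FLC chromatin states in dividing root cell files.

The model represents a root meristem as independent clonal cell files. Each
cell carries the unordered combination of the two FLC gene copies' chromatin
states (both active, one active, or both silenced). At every timestep each
cell first ages and possibly divides (daughters inherit the mother's state;
cells pushed past the top of the file are removed), then undergoes stochastic
per-copy switching: an active copy silences with probability ``p_off`` per
timestep and a silenced copy reactivates with probability ``p_on``.

Protein levels (Venus fluorescence units) are emitted per cell from a
log-normal model: each cell has a log-normal background ``e^X_OFF`` and each
active copy contributes a log-normal signal ``e^X_ON``; a cell with both
copies active doubles a single signal draw (``2 e^X_ON + e^X_OFF``).

All probabilities are *per configured timestep* (default 1 h) and are not
rescaled if the timestep changes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "CellState",
    "SwitchingParams",
    "EmissionParams",
    "CellCycleModel",
    "Cell",
    "CellFileState",
    "SimulationConfig",
    "SimResult",
    "switch_cell",
    "switch_states",
    "transition_matrix",
    "draw_cycle_duration",
    "advance_file",
    "simulate_root",
    "sample_intensity",
    "census",
]

HOURS_PER_DAY = 24.0


class CellState(enum.IntEnum):
    """Unordered two-copy chromatin state; the value is the number of active copies."""

    OFF_OFF = 0
    ON_OFF = 1
    ON_ON = 2


@dataclass(frozen=True)
class SwitchingParams:
    """Per-copy, per-timestep switching probabilities."""

    p_off: float
    p_on: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_off <= 1.0 and 0.0 <= self.p_on <= 1.0):
            raise ValueError(f"switching probabilities must lie in [0, 1]: {self}")


@dataclass(frozen=True)
class EmissionParams:
    """Log-normal emission parameters for per-cell Venus intensity.

    ``mu_on``/``sigma_on`` parameterize the log-intensity of the signal from a
    single active copy, ``mu_off``/``sigma_off`` the cell background.
    """

    mu_on: float
    sigma_on: float
    mu_off: float
    sigma_off: float
    iid_copies: bool = False  # two independent signal draws for ON/ON instead of one doubled

    def __post_init__(self) -> None:
        if self.sigma_on < 0 or self.sigma_off < 0:
            raise ValueError("emission sigmas must be non-negative")


@dataclass(frozen=True)
class CellCycleModel:
    """Position-dependent truncated-normal cell-cycle durations (hours).

    ``mean_by_position`` / ``sd_by_position`` are 1-indexed by position along
    the file (position 1 abuts the quiescent center); scalars broadcast to all
    positions. Positions beyond the table clamp to the nearest defined entry.
    Durations are truncated below at ``min_duration`` (13 h by default, the
    shortest epidermis/cortex cycle reported in the literature the defaults
    are drawn from).
    """

    mean_by_position: np.ndarray = field(default_factory=lambda: np.array([20.0]))
    sd_by_position: np.ndarray = field(default_factory=lambda: np.array([4.0]))
    min_duration: float = 13.0
    method: str = "truncate"  # "truncate" (exact truncated normal) or "clip"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_by_position", np.atleast_1d(np.asarray(self.mean_by_position, dtype=float)))
        object.__setattr__(self, "sd_by_position", np.atleast_1d(np.asarray(self.sd_by_position, dtype=float)))
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if np.any(self.mean_by_position <= 0):
            raise ValueError("cell-cycle means must be positive")
        if np.any(self.sd_by_position < 0):
            raise ValueError("cell-cycle SDs must be non-negative")
        if self.method not in ("truncate", "clip"):
            raise ValueError(f"unknown truncation method {self.method!r}")

    def params_at(self, position: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and SD at 1-based positions, clamped to the table range."""
        idx = np.clip(np.asarray(position) - 1, 0, self.mean_by_position.size - 1)
        sidx = np.clip(np.asarray(position) - 1, 0, self.sd_by_position.size - 1)
        return self.mean_by_position[idx], self.sd_by_position[sidx]


@dataclass
class Cell:
    """A single cell: 1-based position, chromatin state, remaining cycle time (h)."""

    position: int
    state: CellState
    remaining_cycle: float


@dataclass
class CellFileState:
    """Ordered clonal cell file; index 0 is position 1 (adjacent to the QC)."""

    states: np.ndarray  # int8, number of active copies per cell
    remaining: np.ndarray  # float hours

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.remaining = np.asarray(self.remaining, dtype=float)
        if self.states.shape != self.remaining.shape:
            raise ValueError("states and remaining must have identical shape")

    def __len__(self) -> int:
        return self.states.size

    @property
    def cells(self) -> list[Cell]:
        return [
            Cell(position=i + 1, state=CellState(int(s)), remaining_cycle=float(r))
            for i, (s, r) in enumerate(zip(self.states, self.remaining))
        ]

    @classmethod
    def from_cells(cls, cells: list[Cell]) -> "CellFileState":
        return cls(
            states=np.array([c.state for c in cells], dtype=np.int8),
            remaining=np.array([c.remaining_cycle for c in cells]),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation layout: file count/length, timestep, duration and output times.

    ``output_times`` are hours and must be whole multiples of ``timestep``.
    ``exclude_bottom`` cells adjacent to the QC are dropped by :func:`census`,
    mirroring the imaging region.
    """

    n_files: int = 1000
    file_length: int = 30
    timestep: float = 1.0
    duration: float = 21 * HOURS_PER_DAY
    output_times: tuple[float, ...] = (7 * HOURS_PER_DAY, 15 * HOURS_PER_DAY, 21 * HOURS_PER_DAY)
    exclude_bottom: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.exclude_bottom >= self.file_length:
            raise ValueError("exclude_bottom must be smaller than file_length")
        for t in self.output_times:
            k = t / self.timestep
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"output time {t} h is not a whole multiple of timestep {self.timestep} h")
            if t > self.duration + 1e-9:
                raise ValueError(f"output time {t} h exceeds duration {self.duration} h")


@dataclass
class SimResult:
    """States and intensities recorded at each output time.

    ``states[t]`` and ``intensities[t]`` are ``(n_files, file_length)`` arrays;
    entry value in ``states`` is the number of active FLC copies.
    """

    config: SimulationConfig
    switching: SwitchingParams
    emission: EmissionParams | None
    seed: int
    states: dict[float, np.ndarray]
    intensities: dict[float, np.ndarray]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for t in sorted(self.states):
            s = self.states[t]
            nf, nl = s.shape
            frames.append(
                pd.DataFrame(
                    {
                        "file_id": np.repeat(np.arange(nf), nl),
                        "position": np.tile(np.arange(1, nl + 1), nf),
                        "time_h": t,
                        "n_active_copies": s.ravel(),
                        "intensity": (
                            self.intensities[t].ravel() if t in self.intensities else np.nan
                        ),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# switching

def _thresholds(state: int, p_off: float, p_on: float) -> tuple[float, int, float, int]:
    """Cumulative switching thresholds (t1 -> s1, t1+t2 -> s2, else stay).

    The comparison order follows the model's stated scheme: the double switch
    is tested first, then the single switch, else the cell keeps its state.
    """
    if state == CellState.OFF_OFF:
        return p_on * p_on, int(CellState.ON_ON), 2 * p_on * (1 - p_on), int(CellState.ON_OFF)
    if state == CellState.ON_OFF:
        return p_off * (1 - p_on), int(CellState.OFF_OFF), p_on * (1 - p_off), int(CellState.ON_ON)
    if state == CellState.ON_ON:
        return p_off * p_off, int(CellState.OFF_OFF), 2 * p_off * (1 - p_off), int(CellState.ON_OFF)
    raise ValueError(f"unknown state {state!r}")


def switch_cell(state: CellState, params: SwitchingParams, r: float) -> CellState:
    """Apply one switching step to a single cell given a uniform draw ``r``."""
    if not (0.0 <= r < 1.0):
        raise ValueError(f"r must lie in [0, 1): got {r}")
    t1, s1, t2, s2 = _thresholds(int(state), params.p_off, params.p_on)
    if r < t1:
        return CellState(s1)
    if r < t1 + t2:
        return CellState(s2)
    return CellState(state)


def switch_states(states: np.ndarray, params: SwitchingParams, r: np.ndarray) -> np.ndarray:
    """Vectorized :func:`switch_cell` on an array of states with matching uniforms."""
    out = np.array(states, dtype=np.int8, copy=True)
    for s in (CellState.OFF_OFF, CellState.ON_OFF, CellState.ON_ON):
        t1, s1, t2, s2 = _thresholds(int(s), params.p_off, params.p_on)
        m = states == int(s)
        out[m & (r < t1)] = s1
        out[m & (r >= t1) & (r < t1 + t2)] = s2
    return out


def transition_matrix(params: SwitchingParams) -> np.ndarray:
    """3x3 one-step Markov matrix on the number of active copies (rows: from 0,1,2)."""
    M = np.zeros((3, 3))
    for s in range(3):
        t1, s1, t2, s2 = _thresholds(s, params.p_off, params.p_on)
        M[s, s1] += t1
        M[s, s2] += t2
        M[s, s] += 1 - t1 - t2
    return M


# ---------------------------------------------------------------------------
# cell cycle

def _draw_durations(model: CellCycleModel, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mean, sd = model.params_at(positions)
    mean = np.broadcast_to(mean, np.shape(positions)).astype(float)
    sd = np.broadcast_to(sd, np.shape(positions)).astype(float)
    out = np.empty_like(mean)
    degenerate = sd == 0
    out[degenerate] = np.maximum(mean[degenerate], model.min_duration)
    if np.any(~degenerate):
        m, s = mean[~degenerate], sd[~degenerate]
        if model.method == "truncate":
            # exact inverse-CDF sampling of the normal truncated below at min_duration
            f_min = ndtr((model.min_duration - m) / s)
            u = rng.random(m.shape)
            out[~degenerate] = m + s * ndtri(f_min + u * (1.0 - f_min))
        else:  # clip
            out[~degenerate] = np.maximum(rng.normal(m, s), model.min_duration)
    return out


def draw_cycle_duration(model: CellCycleModel, position: int, rng: np.random.Generator) -> float:
    """Draw one cell-cycle duration (hours) for a cell at a 1-based position."""
    return float(_draw_durations(model, np.array([position]), rng)[0])


# ---------------------------------------------------------------------------
# stepping

def advance_file(
    file: CellFileState,
    sw: SwitchingParams,
    cyc: CellCycleModel,
    dt: float,
    rng: np.random.Generator,
    file_length: int = 30,
) -> CellFileState:
    """Advance one cell file by a single timestep: division first, then switching.

    Division: remaining cycles decrease by ``dt``; cells at or below zero
    divide in place (positions above shift up by one per division, accumulated
    from the tip upward), both daughters draw fresh position-dependent
    durations and inherit the mother's state; cells pushed past
    ``file_length`` are removed. Switching: every surviving cell draws one
    uniform and applies the per-copy scheme.
    """
    if len(file) == 0:
        return CellFileState(states=np.empty(0, dtype=np.int8), remaining=np.empty(0))
    rem = file.remaining - dt
    dividing = rem <= 0
    counts = 1 + dividing.astype(int)
    states = np.repeat(file.states, counts)[:file_length]
    rem_new = np.repeat(rem, counts)[:file_length]
    daughter = np.repeat(dividing, counts)[:file_length]
    if np.any(daughter):
        positions = np.nonzero(daughter)[0] + 1
        rem_new[daughter] = _draw_durations(cyc, positions, rng)
    r = rng.random(states.size)
    return CellFileState(states=switch_states(states, sw, r), remaining=rem_new)


def _step_full(
    states: np.ndarray,
    remaining: np.ndarray,
    sw: SwitchingParams,
    cyc: CellCycleModel,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One timestep for a rectangular block of full-length files (vectorized).

    Equivalent to :func:`advance_file` applied per row, given that every file
    holds exactly ``file_length`` cells (which divisions preserve: each
    division inserts one daughter and evicts the top cell).
    """
    nf, nl = states.shape
    remaining = remaining - dt
    dividing = remaining <= 0
    counts = 1 + dividing.astype(np.int64)
    cum = np.cumsum(counts, axis=1)
    # src[f, j] = index of the mother occupying output slot j after the shifts
    src = (cum[:, :, None] <= np.arange(nl)[None, None, :]).sum(axis=1)
    rows = np.arange(nf)[:, None]
    new_states = states[rows, src]
    new_rem = remaining[rows, src]
    daughter = dividing[rows, src]
    if np.any(daughter):
        positions = np.broadcast_to(np.arange(1, nl + 1), (nf, nl))[daughter]
        new_rem = new_rem.copy()
        new_rem[daughter] = _draw_durations(cyc, positions, rng)
    r = rng.random((nf, nl))
    return switch_states(new_states, sw, r), new_rem


# ---------------------------------------------------------------------------
# emission

def sample_intensity(
    state: CellState | np.ndarray,
    em: EmissionParams,
    rng: np.random.Generator,
) -> float | np.ndarray:
    """Sample Venus intensity for cells in the given state(s).

    ON/ON cells double a single active-copy draw (``2 e^{X_ON} + e^{X_OFF}``)
    unless ``em.iid_copies`` requests two independent draws; ON/OFF cells emit
    ``e^{X_ON} + e^{X_OFF}``; OFF/OFF cells emit background only.
    """
    k = np.asarray(state, dtype=float)
    x_off = rng.normal(em.mu_off, em.sigma_off, k.shape)
    if em.iid_copies:
        x1 = rng.normal(em.mu_on, em.sigma_on, k.shape)
        x2 = rng.normal(em.mu_on, em.sigma_on, k.shape)
        signal = np.where(k >= 1, np.exp(x1), 0.0) + np.where(k >= 2, np.exp(x2), 0.0)
    else:
        x_on = rng.normal(em.mu_on, em.sigma_on, k.shape)
        signal = k * np.exp(x_on)
    out = signal + np.exp(x_off)
    if np.isscalar(state) or isinstance(state, CellState):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# whole-root simulation

def simulate_root(
    config: SimulationConfig,
    sw: SwitchingParams,
    em: EmissionParams | None,
    cyc: CellCycleModel | None = None,
) -> SimResult:
    """Simulate ``config.n_files`` files from an all-ON/ON start.

    Every file begins with ``file_length`` ON/ON cells whose remaining cycle
    times are desynchronized (uniform fraction of a freshly drawn duration).
    States and (if ``em`` is given) sampled intensities are recorded at each
    output time. Fully reproducible from ``config.seed``.
    """
    cyc = cyc or CellCycleModel()
    rng = np.random.default_rng(config.seed)
    nf, nl = config.n_files, config.file_length
    states = np.full((nf, nl), int(CellState.ON_ON), dtype=np.int8)
    positions = np.broadcast_to(np.arange(1, nl + 1), (nf, nl))
    durations = _draw_durations(cyc, positions, rng)
    remaining = rng.random((nf, nl)) * durations

    out_steps = {int(round(t / config.timestep)): t for t in config.output_times}
    n_steps = int(round(config.duration / config.timestep))
    result = SimResult(
        config=config, switching=sw, emission=em, seed=config.seed, states={}, intensities={}
    )

    def record(t: float) -> None:
        result.states[t] = states.copy()
        if em is not None:
            result.intensities[t] = sample_intensity(states, em, rng)

    if 0 in out_steps:
        record(out_steps[0])
    for k in range(1, n_steps + 1):
        states, remaining = _step_full(states, remaining, sw, cyc, config.timestep, rng)
        if k in out_steps:
            record(out_steps[k])
    return result


def census(
    result: SimResult, t: float, exclude_bottom: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """State fractions and pooled intensities at output time ``t`` (hours).

    Drops the ``exclude_bottom`` cells adjacent to the QC from every file
    (defaults to the config value) — the imaging region excludes them.
    Returns ``(fractions, intensities)`` where ``fractions[k]`` is the
    fraction of cells with ``k`` active copies (k = 0, 1, 2).
    """
    if t not in result.states:
        raise KeyError(f"time {t} h was not recorded (available: {sorted(result.states)})")
    nb = result.config.exclude_bottom if exclude_bottom is None else exclude_bottom
    s = result.states[t][:, nb:]
    fractions = np.array([(s == k).mean() for k in range(3)])
    if t in result.intensities:
        intens = result.intensities[t][:, nb:].ravel()
    else:
        intens = np.empty(0)
    return fractions, intens
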