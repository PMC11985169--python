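"""Dispersal-constrained range projection (cellular automaton).

Starting from the thresholded current suitability map, empty suitable
cells are colonized stochastically each dispersal step with probability

    P_col = [1 - prod_i (1 - P_Disp(d_i) * P_Prop(age_i))] * P_Inv,

the product running over occupied source cells i within the kernel
radius; d_i is the source-target distance in integer cell rings
(rounded Euclidean), P_Disp the per-ring kernel, P_Prop the age-dependent
propagule production ramp, and P_Inv the target-cell invasibility (1 in
binary mode for suitable cells, habitat/1000 in continuous mode).
Habitat maps change between environment-change periods; occupied cells
whose habitat drops below the suitability threshold are decolonized
("lost").  Land-use barrier cells are never colonizable; in strong mode
they additionally block propagule transit along the source-target line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rasters import GeometryError

DEFAULT_KERNEL = (1.0, 0.4, 0.16, 0.06, 0.03)


@dataclass(frozen=True)
class DispersalConfig:
    disp_kernel: tuple[float, ...] = DEFAULT_KERNEL
    propagule_prod: tuple[float, ...] = (1.0,)
    suitability_threshold: int = 118      # on the 0-1000 scale
    env_chg_steps: int = 2
    disp_steps_per_env: int = 20
    barrier_mode: str = "strong"          # strong | weak
    invasibility_mode: str = "binary"     # binary | continuous
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.disp_kernel):
            raise ValueError("kernel probabilities must lie in [0,1]")
        if not all(0.0 <= p <= 1.0 for p in self.propagule_prod):
            raise ValueError("propagule probabilities must lie in [0,1]")
        if not (0 <= self.suitability_threshold <= 1000):
            raise ValueError("threshold must lie in [0, 1000]")
        if self.barrier_mode not in ("strong", "weak"):
            raise ValueError(f"unknown barrier_mode {self.barrier_mode!r}")
        if self.invasibility_mode not in ("binary", "continuous"):
            raise ValueError(f"unknown invasibility_mode {self.invasibility_mode!r}")


def threshold_from_mtsps(mtsps: float) -> int:
    """Automaton suitability threshold on the 0-1000 integer scale.

    The continuous 0-1 suitability maps are scaled by 1000 for the
    automaton, so the sensitivity+specificity threshold scales the same
    way (e.g. 0.118 -> 118).
    """
    if not (0.0 <= mtsps <= 1.0):
        raise ValueError("mtsps must lie in [0, 1]")
    return int(round(mtsps * 1000))


def _ring(dy: int, dx: int) -> int:
    """Integer distance ring: Euclidean cell distance, half-up rounding."""
    return int(math.floor(math.hypot(dy, dx) + 0.5))


def kernel_offsets(radius: int) -> list[tuple[int, int, int]]:
    """All (dy, dx, ring) with 1 <= ring <= radius."""
    out = []
    span = radius + 1
    for dy in range(-span, span + 1):
        for dx in range(-span, span + 1):
            if dy == 0 and dx == 0:
                continue
            r = _ring(dy, dx)
            if 1 <= r <= radius:
                out.append((dy, dx, r))
    return out


def _line_cells(dy: int, dx: int) -> list[tuple[int, int]]:
    """Cells strictly between (0,0) and (dy,dx) crossed by the segment."""
    n = 8 * max(abs(dy), abs(dx), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    cells = {(int(round(dy * ti)), int(round(dx * ti))) for ti in t}
    cells.discard((0, 0))
    cells.discard((dy, dx))
    return sorted(cells)


def _shift(arr: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Zero-filled shift: out[r, c] = arr[r + dy, c + dx]."""
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    r0, r1 = max(0, -dy), min(rows, rows - dy)
    c0, c1 = max(0, -dx), min(cols, cols - dx)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = arr[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    return out


@dataclass
class DispersalState:
    """Per-cell automaton state.

    ``col_step``: 0 never occupied, 1 initial distribution, >1 the global
    dispersal step of colonization.  ``lost_step``: 0 or the (1-based)
    environment-change period in which the cell was decolonized.
    """

    habitat: np.ndarray            # current 0-1000 suitability
    barrier: np.ndarray            # bool
    occupied: np.ndarray           # bool
    age: np.ndarray                # steps since colonization (int)
    col_step: np.ndarray           # int tags
    lost_step: np.ndarray          # int tags
    step: int = 0                  # global dispersal-step counter

    def suitable(self, threshold: int) -> np.ndarray:
        return self.habitat >= threshold

    def copy(self) -> "DispersalState":
        return DispersalState(self.habitat.copy(), self.barrier.copy(),
                              self.occupied.copy(), self.age.copy(),
                              self.col_step.copy(), self.lost_step.copy(),
                              self.step)

    def to_raster(self) -> np.ndarray:
        """Integer output codes: 0 never occupied, 1 initial, positive
        step tags for colonization, negative period tags for losses."""
        out = np.where(self.lost_step > 0, -self.lost_step, self.col_step)
        return out.astype(int)


def initialize(current_suitability_1000: np.ndarray, barriers: np.ndarray,
               config: DispersalConfig) -> DispersalState:
    """Occupy every suitable non-barrier cell at full maturity."""
    habitat = np.asarray(current_suitability_1000)
    barriers = np.asarray(barriers, dtype=bool)
    if habitat.shape != barriers.shape:
        raise GeometryError("suitability and barrier rasters differ in shape")
    occupied = (habitat >= config.suitability_threshold) & ~barriers
    age = np.where(occupied, len(config.propagule_prod), 0)
    col_step = np.where(occupied, 1, 0)
    return DispersalState(habitat=habitat.copy(), barrier=barriers.copy(),
                          occupied=occupied, age=age.astype(int),
                          col_step=col_step.astype(int),
                          lost_step=np.zeros(habitat.shape, dtype=int))


def _propagule_pressure(state: DispersalState, config: DispersalConfig
                        ) -> np.ndarray:
    """Per-cell P_Prop for occupied cells (0 elsewhere, 0 at age 0)."""
    ramp = np.asarray(config.propagule_prod)
    idx = np.clip(state.age, 0, len(ramp)) - 1
    pp = np.where((state.age >= 1) & state.occupied, ramp[idx], 0.0)
    return pp


def precompute_blocked(barrier: np.ndarray, config: DispersalConfig
                       ) -> dict[tuple[int, int], np.ndarray] | None:
    """Per-offset transit-blocked masks for strong barrier mode.

    blocked[(dy, dx)][r, c] is True when the straight line from source
    (r+dy, c+dx) to target (r, c) crosses a barrier cell.  Barriers are
    static, so this is computed once per simulation.
    """
    if config.barrier_mode != "strong":
        return None
    out = {}
    for dy, dx, ring in kernel_offsets(len(config.disp_kernel)):
        if ring <= 1:
            continue
        blocked = np.zeros(barrier.shape, dtype=bool)
        for ly, lx in _line_cells(dy, dx):
            blocked |= _shift(barrier, ly, lx, fill=False)
        out[(dy, dx)] = blocked
    return out


def colonization_probability_grid(state: DispersalState,
                                  config: DispersalConfig,
                                  blocked_masks=None) -> np.ndarray:
    """P_col for every cell (0 where not an empty suitable target)."""
    kernel = config.disp_kernel
    radius = len(kernel)
    if config.barrier_mode == "strong" and blocked_masks is None:
        blocked_masks = precompute_blocked(state.barrier, config)
    pp = _propagule_pressure(state, config)
    not_col = np.ones(state.habitat.shape)
    for dy, dx, ring in kernel_offsets(radius):
        p = kernel[ring - 1] * _shift(pp, dy, dx)
        if blocked_masks is not None and (dy, dx) in blocked_masks:
            p = np.where(blocked_masks[(dy, dx)], 0.0, p)
        not_col *= 1.0 - p
    suitable = state.suitable(config.suitability_threshold)
    if config.invasibility_mode == "binary":
        p_inv = suitable.astype(float)
    else:
        p_inv = np.clip(state.habitat / 1000.0, 0.0, 1.0)
    target = ~state.occupied & ~state.barrier & suitable
    return np.where(target, (1.0 - not_col) * p_inv, 0.0)


def colonization_probability(target: tuple[int, int], state: DispersalState,
                             config: DispersalConfig) -> float:
    """Closed-form P_col of a single target cell (direct enumeration)."""
    r0, c0 = target
    if state.barrier[r0, c0] or state.occupied[r0, c0]:
        return 0.0
    h = state.habitat[r0, c0]
    if config.invasibility_mode == "binary":
        p_inv = 1.0 if h >= config.suitability_threshold else 0.0
    else:
        p_inv = min(max(h / 1000.0, 0.0), 1.0)
    pp = _propagule_pressure(state, config)
    rows, cols = state.habitat.shape
    not_col = 1.0
    for dy, dx, ring in kernel_offsets(len(config.disp_kernel)):
        r, c = r0 + dy, c0 + dx
        if not (0 <= r < rows and 0 <= c < cols):
            continue
        if pp[r, c] == 0.0:
            continue
        if config.barrier_mode == "strong" and ring > 1:
            if any(0 <= r0 + ly < rows and 0 <= c0 + lx < cols
                   and state.barrier[r0 + ly, c0 + lx]
                   for ly, lx in _line_cells(dy, dx)):
                continue
        not_col *= 1.0 - config.disp_kernel[ring - 1] * pp[r, c]
    return (1.0 - not_col) * p_inv


def step(state: DispersalState, config: DispersalConfig,
         rng: np.random.Generator, blocked_masks=None) -> DispersalState:
    """One synchronous dispersal event.

    Colonization draws use the pre-update state, so newly colonized cells
    cannot seed until the following step; afterwards every occupied cell's
    age increments.
    """
    new = state.copy()
    p = colonization_probability_grid(state, config, blocked_masks)
    draw = rng.random(p.shape)
    colonized = draw < p
    new.step = state.step + 1
    new.age[state.occupied] += 1
    new.occupied |= colonized
    new.age[colonized] = 0
    new.col_step[colonized] = new.step + 1  # tags start at 2 (1 = initial)
    new.lost_step[colonized] = 0
    return new


def apply_env_change(state: DispersalState, new_habitat: np.ndarray,
                     config: DispersalConfig, period: int = 1
                     ) -> DispersalState:
    """Swap in a new habitat map; decolonize cells that became unsuitable."""
    new_habitat = np.asarray(new_habitat)
    if new_habitat.shape != state.habitat.shape:
        raise GeometryError("habitat map shape mismatch")
    new = state.copy()
    new.habitat = new_habitat.copy()
    lost = state.occupied & (new_habitat < config.suitability_threshold)
    new.occupied[lost] = False
    new.age[lost] = 0
    new.lost_step[lost] = period
    return new


@dataclass
class DispersalOutcome:
    ini_count: int
    colonization_frequency: np.ndarray   # fraction of replicates colonizing
    majority_colonized: np.ndarray       # colonized in > 50% of replicates
    per_replicate: pd.DataFrame          # replicate, colonized, lost, occupied
    replicate_seeds: list[int] = field(default_factory=list)
    final_states: list[DispersalState] = field(default_factory=list)

    @property
    def mean_colonized(self) -> float:
        return float(self.per_replicate["colonized"].mean())

    @property
    def mean_lost(self) -> float:
        return float(self.per_replicate["lost"].mean())

    @property
    def mean_net(self) -> float:
        return self.mean_colonized - self.mean_lost

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "ini_dist": self.ini_count,
            "mean_colonized": self.mean_colonized,
            "mean_lost": self.mean_lost,
            "mean_net": self.mean_net,
            "majority_colonized": int(self.majority_colonized.sum()),
        }])


def run(ini_suitability: np.ndarray, habitat_maps: list[np.ndarray],
        barriers: np.ndarray, config: DispersalConfig,
        keep_states: bool = False) -> DispersalOutcome:
    """Full replicated simulation.

    Each environment-change period applies its habitat map then runs
    ``disp_steps_per_env`` dispersal events; replicates are independent
    with seeds spawned deterministically from ``config.seed``.
    """
    if len(habitat_maps) != config.env_chg_steps:
        raise ValueError(f"expected {config.env_chg_steps} habitat maps, "
                         f"got {len(habitat_maps)}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    init = initialize(ini_suitability, barriers, config)
    blocked_masks = precompute_blocked(init.barrier, config)
    ini_count = int(init.occupied.sum())
    freq = np.zeros(init.habitat.shape)
    rows = []
    finals = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = init.copy()
        for period, hmap in enumerate(habitat_maps, start=1):
            state = apply_env_change(state, hmap, config, period=period)
            for _ in range(config.disp_steps_per_env):
                state = step(state, config, rng, blocked_masks)
        colonized = state.occupied & (state.col_step > 1)
        lost = state.lost_step > 0
        freq += colonized
        rows.append({"replicate": rep,
                     "colonized": int(colonized.sum()),
                     "lost": int(lost.sum()),
                     "occupied": int(state.occupied.sum())})
        if keep_states:
            finals.append(state)
    freq /= config.replicates
    return DispersalOutcome(ini_count=ini_count, colonization_frequency=freq,
                            majority_colonized=freq > 0.5,
                            per_replicate=pd.DataFrame(rows),
                            replicate_seeds=seeds, final_states=finals)


def unlimited_dispersal(ini_suitability: np.ndarray,
                        habitat_maps: list[np.ndarray], threshold: int,
                        barriers: np.ndarray | None = None
                        ) -> DispersalOutcome:
    """Null model: every suitable cell is reachable (pure climate envelope).

    Colonized = suitable in the final map but not initially; lost =
    initially occupied but unsuitable in the final map.
    """
    ini = np.asarray(ini_suitability)
    if barriers is None:
        barriers = np.zeros(ini.shape, dtype=bool)
    barriers = np.asarray(barriers, dtype=bool)
    occupied0 = (ini >= threshold) & ~barriers
    if habitat_maps:
        final = (np.asarray(habitat_maps[-1]) >= threshold) & ~barriers
    else:
        final = occupied0
    colonized = final & ~occupied0
    lost = occupied0 & ~final
    freq = colonized.astype(float)
    return DispersalOutcome(
        ini_count=int(occupied0.sum()),
        colonization_frequency=freq,
        majority_colonized=colonized,
        per_replicate=pd.DataFrame([{"replicate": 0,
                                     "colonized": int(colonized.sum()),
                                     "lost": int(lost.sum()),
                                     "occupied": int(final.sum())}]),
        replicate_seeds=[])
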