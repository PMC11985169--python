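"""Synthetic landscapes with known ground truth.

Generates everything the modelling pipeline consumes — smooth correlated
environmental surfaces, presences sampled from a known logistic suitability
function, drifted "future" climates and clumped barrier masks — so that
parameter recovery, screening, classification and dispersal can all be
tested without external rasters.

Smooth fields are white noise convolved with a Gaussian kernel of the
stated correlation length (``scipy.ndimage.gaussian_filter``), then
standardized.  Two of the layers are built from one shared latent field
plus small independent noise so their correlation exceeds the usual 0.7
collinearity screen, and one strictly non-negative layer emulates a
human-footprint index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet, from_arrays
from .rasters import PredictorStack, RasterGeometry, write_stack


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study system.

    Defaults give a 100x100 grid of 5-km cells placed over central China
    (the latitude band of the study species), six environmental layers of
    20-cell correlation length, and 200 presences drawn from a suitability
    surface driven by two independent layers (effects of 3 and -2 landscape
    standard deviations) with an intercept of -5, so that suitable habitat
    covers roughly a tenth of the landscape — the rare-species regime in
    which presence-background modelling is typically applied.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size_km: float = 5.0
    n_layers: int = 6
    layer_smoothness: float = 20.0  # correlation length, in cells
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env_1": 3.0, "env_3": -2.0})
    intercept: float = -5.0  # controls landscape prevalence of suitability
    n_presences: int = 200
    future_shift: dict[str, float] = field(default_factory=lambda: {"env_1": 1.0})
    barrier_fraction: float = 0.25
    origin_lon: float = 105.0
    origin_lat: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")
        if not (0.0 <= self.barrier_fraction < 1.0):
            raise ValueError("barrier_fraction must lie in [0, 1)")
        if self.n_layers < 2:
            raise ValueError("need at least two layers")

    @property
    def geometry(self) -> RasterGeometry:
        cellsize = self.cell_size_km / 111.19  # km -> degrees at the equator
        return RasterGeometry(rows=self.grid_rows, cols=self.grid_cols,
                              xll=self.origin_lon, yll=self.origin_lat,
                              cellsize=cellsize)

    def layer_names(self) -> list[str]:
        names = [f"env_{i}" for i in range(1, self.n_layers)]
        names.append("hfp")  # non-negative human-footprint-like layer
        return names

    def to_file(self, path) -> None:
        """Persist as a plain-text key=value config."""
        lines = []
        for k, v in self.__dict__.items():
            if isinstance(v, dict):
                v = ",".join(f"{kk}:{vv}" for kk, vv in v.items())
            lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if not np.isfinite(smoothness):
        return np.zeros(shape)
    if smoothness <= 0:
        return noise
    f = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = f.std()
    if sd < 1e-12:  # smoothing wiped all variance
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_stack(scenario: SyntheticScenario) -> PredictorStack:
    """Generate the scenario's predictor stack.

    Layers ``env_1..env_{n-1}`` are standardized smooth fields with a
    north-south gradient added; ``env_2`` shares ``env_1``'s latent field
    (plus small noise) so the pair exceeds |r| = 0.7.  The final ``hfp``
    layer is a strictly non-negative squashed field.
    """
    rng = np.random.default_rng(scenario.seed)
    geom = scenario.geometry
    shape = geom.shape
    names = scenario.layer_names()

    gradient = np.linspace(1.0, -1.0, shape[0])[:, None] * np.ones(shape)
    if not np.isfinite(scenario.layer_smoothness):
        # infinite correlation length: perfectly flat landscape
        gradient = np.zeros(shape)

    stack = PredictorStack(geometry=geom)
    latent = _smooth_field(rng, shape, scenario.layer_smoothness)
    for i, name in enumerate(names):
        if name == "hfp":
            f = _smooth_field(rng, shape, scenario.layer_smoothness)
            vals = 50.0 / (1.0 + np.exp(-(f + 0.3 * gradient)))  # in (0, 50)
        elif i == 0:
            vals = latent + 0.3 * gradient
        elif i == 1:
            # correlated twin of env_1: same latent + small noise
            twin_noise = 0.25 if latent.std() > 0 else 0.0
            vals = latent + 0.3 * gradient + twin_noise * rng.standard_normal(shape)
        else:
            vals = _smooth_field(rng, shape, scenario.layer_smoothness) \
                + 0.3 * gradient * ((-1) ** i)
        stack.add(name, vals)
    return stack


def true_suitability(stack: PredictorStack,
                     true_coefficients: dict[str, float],
                     intercept: float = 0.0) -> np.ndarray:
    """Ground-truth suitability: logistic(intercept + sum_k beta_k * layer_k).

    Layers not named in ``true_coefficients`` have zero effect; a negative
    intercept makes suitable habitat rare on the landscape.
    """
    unknown = set(true_coefficients) - set(stack.names)
    if unknown:
        raise KeyError(f"coefficients for unknown layers: {sorted(unknown)}")
    eta = np.full(stack.geometry.shape, float(intercept))
    for name, beta in true_coefficients.items():
        eta = eta + beta * stack[name]
    return 1.0 / (1.0 + np.exp(-eta))


def sample_presences(suitability: np.ndarray, geometry: RasterGeometry,
                     n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` distinct cells with probability proportional to
    suitability (without replacement, one record per cell) and return
    cell-center coordinates."""
    suit = np.asarray(suitability, dtype=float)
    flat = np.where(np.isfinite(suit), suit, 0.0).ravel()
    n_pos = int((flat > 0).sum())
    if n > n_pos:
        raise ValueError(f"cannot draw {n} distinct cells from {n_pos} "
                         "with nonzero suitability")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, suit.shape)
    lon, lat = geometry.cell_centers()
    return from_arrays(lon[rows, cols], lat[rows, cols],
                       provenance=f"synthetic seed={seed}")


def generate_future(stack: PredictorStack,
                    future_shift: dict[str, float] | list[dict[str, float]]
                    ) -> PredictorStack | list[PredictorStack]:
    """Additively drift named layers to fabricate future climate stacks.

    One shift dict gives one stack; a list of dicts gives one stack per
    horizon, in order.  Geometry is preserved exactly.
    """
    if isinstance(future_shift, list):
        return [generate_future(stack, s) for s in future_shift]
    unknown = set(future_shift) - set(stack.names)
    if unknown:
        raise KeyError(f"shift names not in stack: {sorted(unknown)}")
    out = stack.copy()
    for name, delta in future_shift.items():
        out.layers[name] = out.layers[name] + delta
    return out


def generate_barriers(scenario: SyntheticScenario) -> np.ndarray:
    """Clumped binary barrier mask covering ~``barrier_fraction`` of cells.

    A smooth random field is thresholded at the appropriate quantile, which
    yields spatially contiguous patches rather than i.i.d. speckle (the
    field's correlation length is a quarter of the layer smoothness so
    patches are smaller than climate features, like farmland/urban blocks).
    """
    rng = np.random.default_rng(scenario.seed + 0x5EED)
    shape = scenario.geometry.shape
    if scenario.barrier_fraction == 0:
        return np.zeros(shape, dtype=bool)
    sigma = max(1.0, scenario.layer_smoothness / 4.0)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    cut = np.quantile(f, 1.0 - scenario.barrier_fraction)
    return f > cut


def write_scenario_products(scenario: SyntheticScenario, directory) -> dict:
    """Generate and persist every product of a scenario as plain text.

    Returns a dict of the in-memory objects for further use.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = generate_stack(scenario)
    suit = true_suitability(stack, scenario.true_coefficients,
                            intercept=scenario.intercept)
    occ = sample_presences(suit, scenario.geometry, scenario.n_presences,
                           scenario.seed)
    future = generate_future(stack, scenario.future_shift)
    barriers = generate_barriers(scenario)

    write_stack(stack, directory / "current")
    write_stack(future, directory / "future")
    occ.to_csv(directory / "occurrences.csv")
    from .rasters import write_ascii_grid
    write_ascii_grid(directory / "barriers.asc", barriers.astype(float),
                     scenario.geometry)
    scenario.to_file(directory / "scenario.txt")
    return {"stack": stack, "suitability": suit, "occurrences": occ,
            "future": future, "barriers": barriers}
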