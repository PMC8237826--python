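"""Synthetic scenario generator: landscapes, climate layers, communities and
(optionally biased) survey records with known ground truth.

Everything is generated on one planar grid (meters) from a single integer
seed.  Randomness discipline: the seed feeds a ``numpy`` ``SeedSequence``
which is spawned into fixed named child streams (climate, habitat,
infrastructure, vegetation, community, survey), each driving a PCG64
generator — so identical configs give byte-identical outputs and changing,
say, the survey bias does not perturb the landscape.

Habitat is a thresholded smoothed Gaussian random field: white noise blurred
with a Gaussian kernel of width ``fragmentation`` (cells) and cut at the
quantile matching ``habitat_cover``.  Species occupy habitat cells with a
logistic response to a latent climate gradient (random midpoint, width and
direction per species).  Survey sites are drawn without replacement with
probability proportional to

    exp(bias_fragment * z(log fragment size) - bias_access * z(access distance))

over habitat cells, where access distance is the distance to the nearest
road or urban cell; with both coefficients zero the selection is uniform.
Each site yields Poisson(effort_per_site) records of species drawn from the
cell's true community, with jittered coordinates formatted as decimal
strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box, mapping

from gapmeter import landscape
from gapmeter.raster import Raster, write_ascii

__all__ = [
    "ScenarioConfig",
    "SurveyTruth",
    "Scenario",
    "generate_climate_layers",
    "generate_fragmented_habitat",
    "simulate_survey",
    "generate_scenario",
    "write_scenario",
]

_STREAMS = ("climate", "habitat", "infrastructure", "vegetation", "community", "survey")


@dataclass
class ScenarioConfig:
    seed: int = 0
    width: int = 100
    height: int = 100
    cell_size: float = 1000.0
    n_climate_layers: int = 19
    climate_smoothness: float = 12.0
    habitat_cover: float = 0.12
    fragmentation: float = 3.0
    n_species: int = 50
    n_sites: int = 117
    bias_fragment: float = 0.0
    bias_access: float = 0.0
    effort_per_site: float = 30.0
    n_roads: int = 4
    n_urban: int = 6
    coord_decimals: int = 4
    gap_m: float = 180.0

    def __post_init__(self) -> None:
        if not 0.0 < self.habitat_cover < 1.0:
            raise ValueError("habitat_cover must be strictly in (0, 1)")
        for name in ("width", "height", "n_climate_layers", "n_species", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bias_fragment < 0 or self.bias_access < 0:
            raise ValueError("bias coefficients must be >= 0")
        if self.cell_size <= 0 or self.effort_per_site <= 0:
            raise ValueError("cell_size and effort_per_site must be positive")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class SurveyTruth:
    """Ground truth of one synthetic survey, sufficient to score recovery."""

    true_richness: dict[tuple[int, int], int]  # raster (row, col) -> richness
    site_probs: dict[tuple[int, int], float]  # candidate cell -> selection prob
    sites: list[tuple[int, int]]  # chosen site cells
    bias_fragment: float
    bias_access: float

    def to_json(self) -> str:
        payload = {
            "bias_fragment": float(self.bias_fragment),
            "bias_access": float(self.bias_access),
            "sites": [[int(r), int(c)] for r, c in self.sites],
            "true_richness": {
                f"{r},{c}": int(v) for (r, c), v in sorted(self.true_richness.items())
            },
            "site_probs": {f"{r},{c}": float(v) for (r, c), v in sorted(self.site_probs.items())},
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class Scenario:
    config: ScenarioConfig
    habitat: Raster
    roads: Raster
    urban: Raster
    veg_index: Raster
    climate: list[Raster]
    latent_climate: Raster  # gradient driving both climate layers and occupancy
    metrics: dict[str, Raster] = field(default_factory=dict)

    @property
    def polygon(self):
        cfg = self.config
        return box(0.0, 0.0, cfg.width * cfg.cell_size, cfg.height * cfg.cell_size)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized smoothed Gaussian white noise (zero mean, unit variance)."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = field.std()
    if sd == 0:
        raise ValueError("degenerate random field (sigma too large for extent)")
    return (field - field.mean()) / sd


def generate_climate_layers(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[list[Raster], Raster]:
    """Mutually correlated smooth climate layers plus the shared latent gradient."""
    rng = rng or config.rngs()["climate"]
    latent = _smooth_field(rng, config.shape, config.climate_smoothness)
    layers = []
    for _ in range(config.n_climate_layers):
        w = rng.uniform(0.6, 0.95)
        noise = _smooth_field(rng, config.shape, config.climate_smoothness)
        layer = w * latent + np.sqrt(1.0 - w**2) * noise
        layers.append(Raster(layer, config.cell_size))
    return layers, Raster(latent, config.cell_size)


def _draw_line(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Rasterize a 1-cell-wide line segment (Bresenham-style via sampling)."""
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rr = np.round(np.linspace(r0, r1, n)).astype(int)
    cc = np.round(np.linspace(c0, c1, n)).astype(int)
    mask[rr, cc] = 1.0


def generate_fragmented_habitat(
    config: ScenarioConfig, rngs: dict[str, np.random.Generator] | None = None
) -> tuple[Raster, Raster, Raster]:
    """Binary habitat raster plus road and urban masks.

    Habitat realizes the requested cover by thresholding the smoothed field
    at its (1 - habitat_cover) quantile; roads are 1-cell-wide polylines
    crossing the extent; urban cells form small clusters.
    """
    rngs = rngs or config.rngs()
    shape = config.shape
    field_h = _smooth_field(rngs["habitat"], shape, config.fragmentation)
    threshold = np.quantile(field_h, 1.0 - config.habitat_cover)
    habitat = (field_h > threshold).astype(float)
    realized = habitat.mean()
    if abs(realized - config.habitat_cover) > 0.05:
        raise ValueError(
            f"thresholding reached cover {realized:.3f}, requested {config.habitat_cover:.3f}"
        )
    if config.habitat_cover > 0 and habitat.sum() == 0:
        raise ValueError("degenerate field produced an all-zero habitat mask")

    rng_i = rngs["infrastructure"]
    roads = np.zeros(shape)
    h, w = shape
    for _ in range(config.n_roads):
        if rng_i.random() < 0.5:  # roughly horizontal crossing
            _draw_line(roads, rng_i.integers(h), 0, rng_i.integers(h), w - 1)
        else:
            _draw_line(roads, 0, rng_i.integers(w), h - 1, rng_i.integers(w))
    urban = np.zeros(shape)
    for _ in range(config.n_urban):
        r = rng_i.integers(1, h - 1)
        c = rng_i.integers(1, w - 1)
        size = int(rng_i.integers(1, 3))
        urban[max(r - size, 0) : r + size + 1, max(c - size, 0) : c + size + 1] = 1.0

    cs = config.cell_size
    return Raster(habitat, cs), Raster(roads, cs), Raster(urban, cs)


def _occupancy(
    config: ScenarioConfig, latent: np.ndarray, habitat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Boolean species x habitat-cell occupancy from logistic climate responses."""
    g = latent[habitat]
    midpoints = rng.uniform(-1.5, 1.5, size=config.n_species)
    widths = rng.uniform(0.5, 1.5, size=config.n_species)
    directions = rng.choice([-1.0, 1.0], size=config.n_species)
    logits = directions[:, None] * (g[None, :] - midpoints[:, None]) / widths[:, None]
    prob = 0.05 + 0.9 / (1.0 + np.exp(-logits))
    occ = rng.random(prob.shape) < prob
    empty = ~occ.any(axis=0)
    if empty.any():  # guarantee at least one resident species per habitat cell
        occ[np.argmax(prob[:, empty], axis=0), np.flatnonzero(empty)] = True
    return occ


def simulate_survey(
    config: ScenarioConfig,
    habitat: Raster,
    latent_climate: Raster,
    metrics: dict[str, Raster],
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[pd.DataFrame, SurveyTruth]:
    """Draw survey sites (optionally biased) and emit occurrence records.

    Requires the landscape metrics ``fragment_size``, ``dist_road`` and
    ``dist_urban`` computed for every cell.
    """
    rngs = rngs or config.rngs()
    mask = habitat.data > 0.5
    candidates = np.argwhere(mask)
    if config.n_sites > len(candidates):
        raise ValueError(f"n_sites={config.n_sites} exceeds {len(candidates)} habitat cells")

    occ = _occupancy(config, latent_climate.data, mask, rngs["community"])
    cell_index_of = {tuple(rc): i for i, rc in enumerate(candidates)}

    def zscore(values: np.ndarray) -> np.ndarray:
        sd = values.std()
        return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)

    log_frag = metrics["fragment_size"].data[mask]
    access = np.minimum(metrics["dist_road"].data, metrics["dist_urban"].data)[mask]
    weights = np.exp(
        config.bias_fragment * zscore(log_frag) - config.bias_access * zscore(access)
    )
    probs = weights / weights.sum()

    rng_s = rngs["survey"]
    chosen = rng_s.choice(len(candidates), size=config.n_sites, replace=False, p=probs)

    n_rows = habitat.shape[0]
    cs = habitat.cell_size
    fmt = f"%.{config.coord_decimals}f"
    epoch = np.datetime64("1990-01-01")
    rows = []
    for ci in chosen:
        r, c = candidates[ci]
        present = np.flatnonzero(occ[:, ci])
        n_rec = rng_s.poisson(config.effort_per_site)
        if n_rec == 0:
            continue
        species = rng_s.choice(present, size=n_rec, replace=True)
        jitter = rng_s.uniform(-0.45, 0.45, size=(n_rec, 2))
        x = (c + 0.5 + jitter[:, 0]) * cs
        y = (n_rows - r - 0.5 + jitter[:, 1]) * cs
        days = rng_s.integers(0, 29 * 365, size=n_rec)
        for s, xi, yi, d in zip(species, x, y, days):
            rows.append(
                {
                    "species": f"Species {s:03d}",
                    "lat": fmt % yi,
                    "lon": fmt % xi,
                    "date": str(epoch + np.timedelta64(int(d), "D")),
                    "source": "database",
                }
            )
    records = pd.DataFrame(rows, columns=["species", "lat", "lon", "date", "source"])

    truth = SurveyTruth(
        true_richness={tuple(rc): int(occ[:, i].sum()) for i, rc in enumerate(candidates)},
        site_probs={tuple(rc): float(p) for rc, p in zip(map(tuple, candidates), probs)},
        sites=[tuple(candidates[i]) for i in chosen],
        bias_fragment=config.bias_fragment,
        bias_access=config.bias_access,
    )
    return records, truth


def generate_scenario(config: ScenarioConfig, compute_metrics: bool = True) -> Scenario:
    """Generate all layers of a scenario (and, by default, landscape metrics)."""
    rngs = config.rngs()
    climate, latent = generate_climate_layers(config, rngs["climate"])
    habitat, roads, urban = generate_fragmented_habitat(config, rngs)
    veg = Raster(
        0.6 * _smooth_field(rngs["vegetation"], config.shape, config.fragmentation)
        + 0.4 * habitat.data,
        config.cell_size,
    )
    scenario = Scenario(config, habitat, roads, urban, veg, climate, latent)
    if compute_metrics:
        scenario.metrics = landscape.compute_metrics(
            habitat, roads, urban, veg, window_m=3 * config.cell_size, gap_m=config.gap_m
        )
    return scenario


def write_scenario(
    scenario: Scenario,
    records: pd.DataFrame,
    truth: SurveyTruth,
    out_dir: str | Path,
) -> None:
    """Persist a scenario: CSV records, ASCII-grid rasters, JSON truth/polygon."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    write_ascii(scenario.habitat, out / "habitat.asc")
    write_ascii(scenario.roads, out / "roads.asc")
    write_ascii(scenario.urban, out / "urban.asc")
    write_ascii(scenario.veg_index, out / "veg_index.asc")
    for i, layer in enumerate(scenario.climate):
        write_ascii(layer, out / f"climate_{i:02d}.asc")
    (out / "truth.json").write_text(truth.to_json())
    (out / "polygon.geojson").write_text(
        json.dumps({"type": "Feature", "geometry": mapping(scenario.polygon), "properties": {}})
    )
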