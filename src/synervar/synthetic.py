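"""Synthetic gridded landscapes with known causal structure.

Generates everything the analysis pipeline consumes — a regular planar grid,
spatially autocorrelated environmental gradients, a land-cover mosaic,
species range boxes and the richness they imply — from a single seeded
configuration.  The generative model mirrors the causal structure assumed by
macroecological richness analyses: climate drives vegetation (a tunable
climate-to-biotic coupling), climate/vegetation/topography drive a latent
richness suitability surface with additive spatially structured and white
noise, and species ranges are placed preferentially where suitability is
high.  Because the generating effect sizes are known, downstream variation
partitioning has a known qualitative ordering (e.g. a high coupling with
positive climate and vegetation effects must produce a large climate-biotic
shared fraction).

Continuous gradients are Gaussian random fields with an exponential
covariance kernel exp(-d / range); fields are drawn by Cholesky
factorization of the covariance over cell centroids (exact, and fast at the
default 20 x 20 = 400 cells).  Spatially structured noise is built directly
from low-order positive MEM eigenvectors of the grid so that spatial-filter
selection faces exactly the structure it is designed to absorb.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from . import gridding, spatial
from .errors import ConfigurationError, InputError

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "make_grid",
    "simulate_gradient",
    "simulate_biotic_from_climate",
    "simulate_landcover",
    "simulate_ranges",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Generating parameters of the synthetic study region.

    Defaults define the reference conditions used throughout the test
    suite: a 20 x 20 grid of 110-km cells (400 cells), gradients with a
    550-km autocorrelation range (5 cells), 500 species, a strong
    climate-to-vegetation coupling of 0.9, and moderate effect sizes with
    climate > vegetation > topography.
    """

    grid_nx: int = 20
    grid_ny: int = 20
    cell_size: float = 110.0           # km
    seed: int = 0
    sar_range: float = 550.0           # km, gradient autocorrelation range
    n_species: int = 500
    beta_climate: float = 1.0
    beta_biotic: float = 0.8
    beta_topo: float = 0.3
    climate_to_biotic: float = 0.9     # coupling in [0, 1]
    noise_sd: float = 0.3
    spatial_noise_sd: float = 0.3
    n_landcover_classes: int = 11
    coast_band: int = 0                # grid-cell width of a low-terrestrial band
    n_climate_vars: int = 4
    n_biotic_vars: int = 2             # continuous vegetation-structure variables
    n_pixels_per_cell: int = 16        # sub-cell samples for zonal statistics
    range_size_min: float = 110.0      # km, log-uniform box edge bounds
    range_size_max: float = 550.0

    def validate(self, min_cells: int = 1) -> None:
        """Check parameter ranges; ``min_cells`` = 25 for full dataset
        simulation (too few cells make the spatial machinery degenerate),
        1 for bare grid construction."""
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.grid_nx * self.grid_ny < min_cells:
            raise ConfigurationError(f"grid must have at least {min_cells} cells")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.sar_range <= 0:
            raise ConfigurationError("sar_range must be positive")
        if self.n_species <= 0:
            raise ConfigurationError("n_species must be positive")
        if not 0.0 <= self.climate_to_biotic <= 1.0:
            raise ConfigurationError("climate_to_biotic must be in [0, 1]")
        if self.noise_sd < 0 or self.spatial_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.n_landcover_classes < 1:
            raise ConfigurationError("n_landcover_classes must be >= 1")
        if self.range_size_min <= 0 or self.range_size_max < self.range_size_min:
            raise ConfigurationError("invalid range size bounds")


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def make_grid(config: SimConfig) -> pd.DataFrame:
    """Regular nx x ny grid of square cells on a planar km frame.

    Centroids sit at (col + 1/2, row + 1/2) * cell_size.  All cells are
    fully terrestrial unless ``coast_band`` > 0, in which case cells within
    that many rows/columns of the domain edge get a sub-threshold
    terrestrial fraction (a synthetic coastline).
    """
    config.validate()
    nx, ny, cs = config.grid_nx, config.grid_ny, config.cell_size
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    cols, rows = cols.ravel(), rows.ravel()
    frac = np.ones(nx * ny)
    if config.coast_band > 0:
        edge = (
            (cols < config.coast_band)
            | (rows < config.coast_band)
            | (cols >= nx - config.coast_band)
            | (rows >= ny - config.coast_band)
        )
        frac[edge] = 0.25
    return pd.DataFrame(
        {
            "cell_id": np.arange(nx * ny),
            "x_km": (cols + 0.5) * cs,
            "y_km": (rows + 0.5) * cs,
            "terrestrial_frac": frac,
        }
    )


def _coords(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_km", "y_km"]].to_numpy(dtype=float)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


# Cholesky factors of the gradient covariance are cached per (coords, range):
# the grid is fixed across gradients and Monte-Carlo replicates, so the
# factorization dominates cost only once.
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _chol_factor(coords: np.ndarray, range_km: float) -> np.ndarray:
    key = (coords.shape[0], float(range_km), hash(coords.tobytes()))
    if key not in _CHOL_CACHE:
        d = spatial.pairwise_distances(coords)
        c = np.exp(-d / range_km)
        c[np.diag_indices_from(c)] += 1e-8  # numerical jitter
        if len(_CHOL_CACHE) > 32:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = cholesky(c, lower=True)
    return _CHOL_CACHE[key]


def simulate_gradient(cells: pd.DataFrame, range_km: float, seed) -> np.ndarray:
    """Zero-mean unit-variance spatially autocorrelated field over cells.

    A Gaussian random field with exponential covariance exp(-d / range_km),
    standardized exactly after the draw.  ``seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    if range_km <= 0:
        raise ConfigurationError("range_km must be positive")
    if len(cells) < 2:
        raise InputError("need at least 2 cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = _chol_factor(_coords(cells), range_km)
    return _zscore(chol @ rng.standard_normal(len(cells)))


def simulate_biotic_from_climate(
    climate_cols: np.ndarray,
    coupling: float,
    seed,
    cells: pd.DataFrame,
    n_out: int = 1,
    sar_range: float = 550.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vegetation gradients partially driven by climate.

    Each output is ``coupling * mix + sqrt(1 - coupling^2) * independent``
    where ``mix`` is the standardized mean of the standardized climate
    columns and the independent part is a fresh autocorrelated gradient;
    outputs are standardized to unit variance.  Returns ``(biotic, mix)`` so
    the generating correlation (= coupling) can be checked directly.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ConfigurationError("coupling must be in [0, 1]")
    climate = np.asarray(climate_cols, dtype=float)
    if climate.ndim == 1:
        climate = climate[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = (climate - climate.mean(axis=0)) / climate.std(axis=0)
    mix = _zscore(z.mean(axis=1))
    out = np.empty((climate.shape[0], n_out))
    for j in range(n_out):
        indep = simulate_gradient(cells, sar_range, rng)
        out[:, j] = _zscore(coupling * mix + np.sqrt(1.0 - coupling**2) * indep)
    return out, mix


def simulate_landcover(
    cells: pd.DataFrame,
    n_classes: int,
    seed,
    sar_range: float = 550.0,
    concentration: float = 2.0,
    climate_mix: np.ndarray | None = None,
    coupling: float = 0.0,
) -> pd.DataFrame:
    """Per-cell land-cover class proportions with autocorrelated dominance.

    Each class gets a latent autocorrelated field (optionally coupled to the
    climate mix); a softmax with the given concentration converts fields to
    proportions, so nearby cells share dominant classes.  Rows sum to 1.
    """
    if n_classes < 1:
        raise ConfigurationError("n_classes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cells)
    if n_classes == 1:
        return pd.DataFrame({"p_class_1": np.ones(n)}).set_index(cells["cell_id"])
    fields = np.empty((n, n_classes))
    for k in range(n_classes):
        g = simulate_gradient(cells, sar_range, rng)
        if climate_mix is not None and coupling > 0:
            sign = 1.0 if k % 2 == 0 else -1.0
            g = _zscore(coupling * sign * climate_mix + np.sqrt(1 - coupling**2) * g)
        fields[:, k] = g
    e = np.exp(concentration * (fields - fields.max(axis=1, keepdims=True)))
    p = e / e.sum(axis=1, keepdims=True)
    out = pd.DataFrame(p, columns=[f"p_class_{k + 1}" for k in range(n_classes)])
    out.index = cells["cell_id"].to_numpy()
    return out


def simulate_ranges(
    cells: pd.DataFrame,
    latent_driver: np.ndarray,
    n_species: int,
    seed,
    cell_size: float = 110.0,
    size_min: float = 110.0,
    size_max: float = 550.0,
) -> pd.DataFrame:
    """Axis-aligned species range boxes placed preferentially where the
    latent suitability driver is high.

    Box centers are drawn over cells with probability proportional to
    exp(z(driver)) — species placement is thinned against the driver — then
    jittered within the cell; box edge lengths are log-uniform between
    ``size_min`` and ``size_max`` km.  Richness computed from the boxes
    therefore correlates positively with the driver.  Large boxes smear the
    driver-richness link over space, so the default maximum edge is five
    cells (a quarter of the default domain).
    """
    if n_species <= 0:
        raise ConfigurationError("n_species must be positive")
    driver = np.asarray(latent_driver, dtype=float).ravel()
    if driver.size != len(cells):
        raise InputError("latent_driver must be defined on all cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(driver) > 0:
        w = np.exp(_zscore(driver))
    else:
        w = np.ones(driver.size)
    p = w / w.sum()
    centers = rng.choice(driver.size, size=n_species, p=p)
    cx = cells["x_km"].to_numpy()[centers] + rng.uniform(-cell_size / 2, cell_size / 2, n_species)
    cy = cells["y_km"].to_numpy()[centers] + rng.uniform(-cell_size / 2, cell_size / 2, n_species)
    log_lo, log_hi = np.log(size_min), np.log(size_max)
    sx = np.exp(rng.uniform(log_lo, log_hi, n_species))
    sy = np.exp(rng.uniform(log_lo, log_hi, n_species))
    return pd.DataFrame(
        {
            "species_id": [f"sp{j:04d}" for j in range(n_species)],
            "xmin": cx - sx / 2,
            "ymin": cy - sy / 2,
            "xmax": cx + sx / 2,
            "ymax": cy + sy / 2,
        }
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one synthetic study region comprises, plus ground truth."""

    config: SimConfig
    cells: pd.DataFrame       # cell_id, x_km, y_km, terrestrial_frac, richness
    env: pd.DataFrame         # clim_* and topo_* observed variables per cell
    landcover: pd.DataFrame   # p_class_* proportions per cell
    ranges: pd.DataFrame      # species range boxes
    truth: dict = field(repr=False)

    def write(self, out_dir) -> None:
        """Write the standard CSV/JSON bundle (deterministic byte-for-byte)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False, float_format="%.10g")
        env = self.env.reset_index().rename(columns={"index": "cell_id"})
        env.to_csv(out / "env.csv", index=False, float_format="%.10g")
        lc = self.landcover.reset_index().rename(columns={"index": "cell_id"})
        lc.to_csv(out / "landcover.csv", index=False, float_format="%.10g")
        self.ranges.to_csv(out / "ranges.csv", index=False, float_format="%.10g")
        truth = {k: v for k, v in self.truth.items() if not isinstance(v, np.ndarray)}
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one complete synthetic study region from the configuration.

    Generative sequence:

    1. climate: ``n_climate_vars`` independent gradients, observed through
       mild monotone transforms (temperature-like, precipitation-like).
    2. topography: an elevation gradient plus a roughness gradient; observed
       topographic variables (mean / range / cv of elevation) are zonal
       statistics over sub-cell pixel samples whose spread follows the
       roughness field.
    3. vegetation: continuous structure gradients coupled to climate with
       the configured coupling, plus a land-cover mosaic whose dominance
       fields share that coupling.
    4. latent suitability = beta_climate * climate_mix + beta_biotic *
       biotic_mix + beta_topo * topo_mix + MEM-structured spatial noise +
       white noise.
    5. species range boxes thinned against the suitability driver; richness
       is the box count per cell (any-overlap rule).
    """
    config.validate(min_cells=25)
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_clim, r_topo, r_bio, r_lc, r_noise, r_rng = rngs

    cells = make_grid(config)
    coords = _coords(cells)

    # -- climate -----------------------------------------------------------
    # Observed climate variables share two latent factors (as real climate
    # variables do: a dominant energy/water factor plus a secondary one) so
    # that a per-set PCA with k=3 axes can capture the climate signal.
    lat1 = simulate_gradient(cells, config.sar_range, r_clim)
    lat2 = simulate_gradient(cells, config.sar_range, r_clim)
    clim_g = np.empty((len(cells), config.n_climate_vars))
    for j in range(config.n_climate_vars):
        e_j = simulate_gradient(cells, config.sar_range, r_clim)
        sign = 1.0 if j % 2 == 0 else -1.0
        clim_g[:, j] = _zscore(
            np.sqrt(0.70) * lat1 + sign * np.sqrt(0.15) * lat2 + np.sqrt(0.15) * e_j
        )
    climate_mix = _zscore(clim_g.mean(axis=1))
    env = pd.DataFrame(index=cells["cell_id"].to_numpy())
    obs_names = ["temp_mean", "temp_range", "precip", "precip_range"]
    for j in range(config.n_climate_vars):
        g = clim_g[:, j]
        if j == 0:
            v = 24.0 + 6.0 * g
        elif j == 1:
            v = 12.0 + 3.0 * g
        elif j == 2:
            v = 1400.0 * np.exp(0.5 * g)
        else:
            v = 600.0 * np.exp(0.4 * g)
        name = obs_names[j] if j < len(obs_names) else f"clim_extra{j}"
        env[f"clim_{name}"] = v

    # -- topography --------------------------------------------------------
    g_elev = simulate_gradient(cells, config.sar_range, r_topo)
    g_rough = simulate_gradient(cells, config.sar_range, r_topo)
    topo_mix = _zscore(g_elev + g_rough)
    base = np.maximum(50.0, 800.0 + 500.0 * g_elev)
    pix_sd = 60.0 * np.exp(0.7 * g_rough)
    pixels = {
        int(cid): np.maximum(1.0, base[i] + pix_sd[i] * r_topo.standard_normal(config.n_pixels_per_cell))
        for i, cid in enumerate(cells["cell_id"])
    }
    from .predictors import zonal_summary

    env["topo_elev_mean"] = zonal_summary(pixels, "mean").reindex(env.index).to_numpy()
    env["topo_elev_range"] = zonal_summary(pixels, "range").reindex(env.index).to_numpy()
    env["topo_elev_cv"] = zonal_summary(pixels, "cv").reindex(env.index).to_numpy()

    # -- vegetation --------------------------------------------------------
    bio_g, _ = simulate_biotic_from_climate(
        clim_g, config.climate_to_biotic, r_bio, cells,
        n_out=config.n_biotic_vars, sar_range=config.sar_range,
    )
    biotic_mix = _zscore(bio_g.mean(axis=1))
    env["bio_canopy_sd"] = 8.0 * np.exp(0.5 * bio_g[:, 0])
    if config.n_biotic_vars > 1:
        env["bio_canopy_range"] = np.maximum(0.5, 25.0 + 8.0 * bio_g[:, 1])
    landcover = simulate_landcover(
        cells, config.n_landcover_classes, r_lc, sar_range=config.sar_range,
        climate_mix=climate_mix, coupling=config.climate_to_biotic,
    )

    # -- latent suitability ------------------------------------------------
    spec = spatial.connectivity(coords)
    basis = spatial.build_mem(spec)
    pos = basis.positive()
    n_noise_vecs = min(15, len(pos))
    weights = r_noise.standard_normal(n_noise_vecs)
    spatial_noise = _zscore(basis.vectors[:, pos[:n_noise_vecs]] @ weights)

    driver = (
        config.beta_climate * climate_mix
        + config.beta_biotic * biotic_mix
        + config.beta_topo * topo_mix
        + config.spatial_noise_sd * spatial_noise
        + config.noise_sd * r_noise.standard_normal(len(cells))
    )
    driver = _zscore(driver)

    # -- ranges and richness ----------------------------------------------
    ranges = simulate_ranges(
        cells, driver, config.n_species, r_rng,
        cell_size=config.cell_size,
        size_min=config.range_size_min, size_max=config.range_size_max,
    )
    cells = cells.copy()
    cells["richness"] = gridding.rasterize_richness(cells, ranges, config.cell_size)

    truth = {
        **asdict(config),
        "climate_mix": climate_mix,
        "biotic_mix": biotic_mix,
        "topo_mix": topo_mix,
        "driver": driver,
        "mst_truncation_km": spec.truncation_km,
    }
    return SyntheticDataset(
        config=config, cells=cells, env=env, landcover=landcover, ranges=ranges, truth=truth
    )
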