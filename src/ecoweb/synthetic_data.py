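"""Synthetic networks, site tables and rasters with known ground truth.

These generators stand in for the field's public data sources (interaction
databases, gridded climate layers, the human-footprint grid) so that every
pipeline stage can be exercised against a known answer: planted nestedness
or module structure in networks, known regression coefficients with
spatially autocorrelated noise in site tables, and analytic gradients in
raster pairs.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecoweb.geo_velocity import EARTH_RADIUS_KM, RasterGrid
from ecoweb.network_io import BipartiteNetwork, DirectedNetwork, SiteRecord
from ecoweb.spatial_regression import DEFAULT_PREDICTORS, DesignTable, great_circle_km
from ecoweb.structure_metrics import Partition

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


def _redraw_until_valid(rng, p: np.ndarray, max_attempts: int = 1000) -> np.ndarray:
    for _ in range(max_attempts):
        mat = (rng.random(p.shape) < p).astype(np.int8)
        if mat.sum() >= 1 and mat.sum(axis=1).min() > 0 and mat.sum(axis=0).min() > 0:
            return mat
    raise RuntimeError("could not draw a matrix without empty rows/columns")


def gen_bipartite_nested(
    n_plants: int,
    n_animals: int,
    connectance: float,
    nestedness_bias: float,
    seed: int,
) -> BipartiteNetwork:
    """Random bipartite network with tunable nestedness.

    Cell probabilities decay exponentially with the sum of normalized row
    and column ranks at rate ``nestedness_bias`` and are rescaled so the
    expected fill equals ``connectance``; bias 0 gives uniform random fill,
    large bias approaches a perfectly nested staircase.
    """
    if not 0.0 < connectance <= 1.0:
        raise ValueError("connectance must lie in (0, 1]")
    if nestedness_bias < 0:
        raise ValueError("nestedness bias must be >= 0")
    if connectance * n_plants * n_animals < 1.0:
        raise ValueError("expected fill below one link")
    rng = np.random.default_rng(seed)
    i = np.arange(n_plants) / max(n_plants - 1, 1)
    j = np.arange(n_animals) / max(n_animals - 1, 1)
    w = np.exp(-nestedness_bias * (i[:, None] + j[None, :]))
    # bisect the scale factor so that mean(min(1, c*w)) == connectance,
    # keeping expected fill on target even where probabilities saturate
    lo, hi = 0.0, 1.0 / w.min()
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if np.minimum(1.0, mid * w).mean() < connectance:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * w)
    try:
        mat = _redraw_until_valid(rng, p, max_attempts=200)
        row_labels = tuple(f"P{i}" for i in range(n_plants))
        col_labels = tuple(f"A{j}" for j in range(n_animals))
    except RuntimeError:
        # at strong bias a sparse perfect staircase cannot give every
        # specialist a link; drop degree-0 species as the readers do
        while True:
            mat = (rng.random(p.shape) < p).astype(np.int8)
            rows = mat.sum(axis=1) > 0
            cols = mat.sum(axis=0) > 0
            if rows.sum() >= 2 and cols.sum() >= 2:
                break
        row_labels = tuple(f"P{i}" for i in np.nonzero(rows)[0])
        col_labels = tuple(f"A{j}" for j in np.nonzero(cols)[0])
        mat = mat[np.ix_(rows, cols)]
    return BipartiteNetwork(row_labels, col_labels, mat)


def gen_bipartite_modular(
    sizes: list[tuple[int, int]],
    p_within: float,
    p_between: float,
    seed: int,
) -> tuple[BipartiteNetwork, Partition]:
    """Planted-partition bipartite network.

    ``sizes`` lists (n_plants, n_animals) per module; links appear with
    probability ``p_within`` inside a module and ``p_between`` across.
    Returns the network together with the planted partition.
    """
    if not sizes or any(r < 1 or c < 1 for r, c in sizes):
        raise ValueError("every module needs at least one plant and one animal")
    if not (0 <= p_between < p_within <= 1):
        raise ValueError("need p_within > p_between >= 0")
    rng = np.random.default_rng(seed)
    row_mod = np.concatenate([[m] * r for m, (r, _) in enumerate(sizes)])
    col_mod = np.concatenate([[m] * c for m, (_, c) in enumerate(sizes)])
    p = np.where(row_mod[:, None] == col_mod[None, :], p_within, p_between)
    mat = _redraw_until_valid(rng, p)
    net = BipartiteNetwork(
        tuple(f"P{i}" for i in range(len(row_mod))),
        tuple(f"A{j}" for j in range(len(col_mod))),
        mat,
    )
    return net, Partition(row_mod, col_mod)


def gen_foodweb(n: int, connectance: float, mutual_fraction: float, seed: int) -> DirectedNetwork:
    """Random directed food web with a controlled fraction of mutual edges.

    ``connectance`` is the expected directed-edge density over the n(n-1)
    ordered pairs; ``mutual_fraction`` the expected fraction of edges that
    belong to mutual (A<->B) pairs.  No self-edges.
    """
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if not 0 <= mutual_fraction < 1:
        raise ValueError("mutual_fraction must lie in [0, 1)")
    mu = mutual_fraction / (2.0 - mutual_fraction)  # share of connected pairs mutual
    q = 2.0 * connectance / (1.0 + mu)  # probability an unordered pair is connected
    if not 0 < q <= 1:
        raise ValueError("infeasible connectance / mutual_fraction combination")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() >= q:
                continue
            if rng.random() < mu:
                adj[i, j] = adj[j, i] = 1
            elif rng.random() < 0.5:
                adj[i, j] = 1
            else:
                adj[j, i] = 1
    if adj.sum() == 0:  # guarantee validity for downstream metrics
        i, j = rng.choice(n, size=2, replace=False)
        adj[i, j] = 1
    return DirectedNetwork(tuple(f"S{i}" for i in range(n)), adj)


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic site table.

    ``betas`` are effects on the standardized scale (predictors and response
    are generated with unit variance, so the regression's standardized
    coefficients estimate them directly).  The residual is split between a
    Gaussian process with exponential covariance (range in km) and white
    noise; by default the total error variance tops the response variance up
    to 1 so that sd(response) is approximately 1.
    """

    betas: dict = field(default_factory=dict)
    spatial_range_km: float = 1100.0
    error_spatial_share: float = 0.5
    total_error_sd: float | None = None
    predictor_spatial_share: float = 0.5
    window: tuple[float, float, float, float] = (0.0, 40.0, 0.0, 40.0)  # lat0, lat1, lon0, lon1
    response_column: str = "Z_NODF"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.betas) - set(DEFAULT_PREDICTORS)
        if unknown:
            raise ValueError(f"betas refer to unknown predictors: {sorted(unknown)}")
        if not 0 <= self.error_spatial_share <= 1 or not 0 <= self.predictor_spatial_share <= 1:
            raise ValueError("spatial shares must lie in [0, 1]")


def _gp_field(rng, coords_km_chol: np.ndarray) -> np.ndarray:
    return coords_km_chol @ rng.standard_normal(coords_km_chol.shape[0])


def gen_site_table(n_sites: int, truth: SyntheticTruth) -> tuple[list[SiteRecord], DesignTable]:
    """Synthetic site table with known coefficients and spatial error.

    Coordinates are uniform on the window; each predictor is a unit-variance
    mix of a smooth spatial field and white noise; the response is the
    linear combination given by ``truth.betas`` plus spatially
    autocorrelated and white Gaussian error.  Records carry the full
    site-table column schema and pass validation unchanged.
    """
    rng = np.random.default_rng(truth.seed)
    lat0, lat1, lon0, lon1 = truth.window
    lats = rng.uniform(lat0, lat1, n_sites)
    lons = rng.uniform(lon0, lon1, n_sites)
    coords = np.column_stack([lats, lons])
    d = great_circle_km(coords)
    cov = np.exp(-d / truth.spatial_range_km)
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n_sites))

    fields = {}
    sp = truth.predictor_spatial_share
    for name in DEFAULT_PREDICTORS:
        z = math.sqrt(sp) * _gp_field(rng, chol) + math.sqrt(1 - sp) * rng.standard_normal(n_sites)
        fields[name] = (z - z.mean()) / z.std()

    signal = sum(b * fields[name] for name, b in truth.betas.items()) if truth.betas else np.zeros(n_sites)
    if truth.total_error_sd is None:
        err_var = max(0.1, 1.0 - float(np.var(signal)))
    else:
        err_var = truth.total_error_sd**2
    sp_err = math.sqrt(err_var * truth.error_spatial_share) * _gp_field(rng, chol)
    wh_err = math.sqrt(err_var * (1 - truth.error_spatial_share)) * rng.standard_normal(n_sites)
    response = signal + sp_err + wh_err
    other = rng.standard_normal(n_sites)  # unstructured placeholder metric

    records = []
    for i in range(n_sites):
        t_vel = math.exp(0.8 * fields["log_T_velocity"][i])
        p_vel = math.exp(0.8 * fields["log_P_velocity"][i])
        z_nodf = response[i] if truth.response_column == "Z_NODF" else other[i]
        z_m = response[i] if truth.response_column == "Z_M" else other[i]
        rec = SiteRecord(
            network_id=f"net{i:04d}",
            network_kind="pollination",
            binary=True,
            Z_NODF=float(z_nodf),
            Z_M=float(z_m),
            n_species=int(max(5, round(40 + 12 * fields["n_species"][i]))),
            n_links=int(max(1, round(80 + 20 * rng.standard_normal()))),
            longitude=float(lons[i]),
            latitude=float(lats[i]),
            elevation=float(800 + 400 * fields["elevation"][i]),
            T_mean=float(150 + 60 * fields["T_mean"][i]),
            T_seasonality=float(5000 + 1500 * fields["T_seasonality"][i]),
            P_ann=float(max(0.0, 1200 + 400 * fields["P_ann"][i])),
            P_seasonality=float(50 + 15 * fields["P_seasonality"][i]),
            human_impact=float(np.clip(50 + 14 * fields["human_impact"][i], 0, 100)),
            T_velocity=float(t_vel),
            P_velocity=float(p_vel),
            mainland_island="mainland" if i % 3 else "island",
        )
        rec.validate()
        records.append(rec)
    # tables too small to regress on are still useful as I/O fixtures
    if n_sites >= len(DEFAULT_PREDICTORS) + 10:
        design = design_from_records(records, response=truth.response_column)
    else:
        design = None
    return records, design


def design_from_records(records, response: str = "Z_NODF") -> DesignTable:
    """Assemble the regression design from site records.

    Velocities enter log-transformed; the design is left unstandardized
    (standardization happens inside the regression suite).
    """
    from ecoweb.geo_velocity import log_transform
    from ecoweb.network_io import _records_to_frame

    df = _records_to_frame(list(records)) if not isinstance(records, pd.DataFrame) else records
    pred = pd.DataFrame(
        {
            "n_species": df["n_species"].astype(float),
            "elevation": df["elevation"].astype(float),
            "T_mean": df["T_mean"].astype(float),
            "T_seasonality": df["T_seasonality"].astype(float),
            "P_ann": df["P_ann"].astype(float),
            "P_seasonality": df["P_seasonality"].astype(float),
            "human_impact": df["human_impact"].astype(float),
            "log_T_velocity": log_transform(df["T_velocity"].to_numpy(dtype=float)),
            "log_P_velocity": log_transform(df["P_velocity"].to_numpy(dtype=float)),
        }
    )
    coords = np.column_stack([df["latitude"].to_numpy(float), df["longitude"].to_numpy(float)])
    return DesignTable(df[response].astype(float).rename(response), pred, coords)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def gen_raster_pair(
    shape: tuple[int, int],
    gradient: float,
    lgm_offset: float | np.ndarray,
    seed: int,
    noise_sd: float = 0.0,
    cell_size: float = 0.5,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[RasterGrid, RasterGrid]:
    """Current/LGM raster pair with an analytic south-north gradient.

    The current surface increases northward at ``gradient`` units per km
    (plus optional white noise); the LGM surface is the current one minus
    ``lgm_offset``.  With zero noise the velocity at every interior cell is
    |offset| / |gradient|.
    """
    nrows, ncols = shape
    if nrows < 3 or ncols < 3:
        raise ValueError("raster must be at least 3x3")
    rng = np.random.default_rng(seed)
    dy_km = cell_size * KM_PER_DEG
    y_km = (nrows - 1 - np.arange(nrows))[:, None] * dy_km
    current = gradient * np.broadcast_to(y_km, (nrows, ncols)).astype(float).copy()
    if noise_sd > 0:
        current += noise_sd * rng.standard_normal((nrows, ncols))
    lgm = current - np.asarray(lgm_offset, dtype=float)
    return (
        RasterGrid(current, cell_size, origin),
        RasterGrid(lgm, cell_size, origin),
    )
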