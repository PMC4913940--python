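"""Containers and file I/O for binary ecological networks and site tables.

Mutualistic networks (pollination, seed dispersal) are bipartite: links run
only between plants (rows) and animals (columns).  Food webs are directed
unipartite networks (resource -> consumer) that may contain mutual edges.
All networks are binary; any positive interaction weight found on disk is
truncated to presence (1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORK_KINDS = ("foodweb", "pollination", "seed_dispersal")

#: Mandatory site-table columns (supplementary-table schema).  Bipartite
#: tables may replace ``n_species`` by ``n_plants`` + ``n_animals``.
SITE_COLUMNS = (
    "network_id",
    "network_kind",
    "binary",
    "Z_NODF",
    "Z_M",
    "n_species",
    "n_links",
    "longitude",
    "latitude",
    "elevation",
    "T_mean",
    "T_seasonality",
    "P_ann",
    "P_seasonality",
    "human_impact",
    "T_velocity",
    "P_velocity",
)
OPTIONAL_SITE_COLUMNS = ("n_plants", "n_animals", "mainland_island")


class NetworkFormatError(ValueError):
    """Raised when a network or site-table file violates the format contract."""


def _as_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise NetworkFormatError(f"expected a 2-D matrix, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise NetworkFormatError("matrix entries must be numeric")
    if np.any(arr < 0):
        raise NetworkFormatError("matrix entries must be nonnegative")
    return (arr > 0).astype(np.int8)


@dataclass(eq=False)
class BipartiteNetwork:
    """Binary plant x animal incidence matrix with row/column labels."""

    plant_labels: tuple
    animal_labels: tuple
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.plant_labels = tuple(self.plant_labels)
        self.animal_labels = tuple(self.animal_labels)
        self.incidence = _as_binary(self.incidence)
        r, c = self.incidence.shape
        if r < 1 or c < 1:
            raise NetworkFormatError("incidence matrix must be at least 1x1")
        if len(self.plant_labels) != r or len(self.animal_labels) != c:
            raise NetworkFormatError("label lengths do not match matrix shape")
        if len(set(self.plant_labels)) != r or len(set(self.animal_labels)) != c:
            raise NetworkFormatError("duplicate plant or animal labels")
        if self.incidence.sum() < 1:
            raise NetworkFormatError("network has no links")

    @property
    def n_plants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_animals(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / (self.n_plants * self.n_animals)

    @property
    def plant_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    @property
    def animal_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    def transpose(self) -> "BipartiteNetwork":
        return BipartiteNetwork(self.animal_labels, self.plant_labels, self.incidence.T)


@dataclass(eq=False)
class DirectedNetwork:
    """Binary directed adjacency; entry (i, j) = 1 means resource i is consumed by j."""

    node_labels: tuple
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        self.adjacency = _as_binary(self.adjacency)
        n, m = self.adjacency.shape
        if n != m:
            raise NetworkFormatError("adjacency matrix must be square")
        if n < 2:
            raise NetworkFormatError("directed network needs at least 2 nodes")
        if len(self.node_labels) != n:
            raise NetworkFormatError("label length does not match matrix")
        if len(set(self.node_labels)) != n:
            raise NetworkFormatError("duplicate node labels")
        if np.any(np.diag(self.adjacency) != 0):
            raise NetworkFormatError("self-edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def edge_triples(self) -> pd.DataFrame:
        """Per-node counts of one-way-in, one-way-out and mutual edges.

        These three counts are the invariants preserved by the directed
        edge-switching null model.
        """
        a = self.adjacency
        mutual = (a & a.T).astype(np.int8)
        oneway = a - mutual
        return pd.DataFrame(
            {
                "oneway_in": oneway.sum(axis=0),
                "oneway_out": oneway.sum(axis=1),
                "mutual": mutual.sum(axis=1),
            },
            index=list(self.node_labels),
        )


def read_incidence_matrix(path: str | Path, sep: str | None = None) -> BipartiteNetwork:
    """Read a labeled 0/1 (or count) table as a binary bipartite network.

    First row and first column hold labels.  Positive counts are truncated
    to 1; all-zero rows/columns are dropped with a logged warning.
    """
    try:
        df = pd.read_csv(path, index_col=0, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise NetworkFormatError(f"cannot parse incidence matrix {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise NetworkFormatError(f"{path}: empty incidence table")
    if df.isna().any().any():
        raise NetworkFormatError(f"{path}: non-rectangular table or missing entries")
    mat = _as_binary(df.to_numpy())
    if mat.sum() == 0:
        raise NetworkFormatError(f"{path}: all-zero incidence matrix")
    row_keep = mat.sum(axis=1) > 0
    col_keep = mat.sum(axis=0) > 0
    if not row_keep.all():
        dropped = [str(x) for x in df.index[~row_keep]]
        logger.warning("dropping %d all-zero rows: %s", len(dropped), dropped)
    if not col_keep.all():
        dropped = [str(x) for x in df.columns[~col_keep]]
        logger.warning("dropping %d all-zero columns: %s", len(dropped), dropped)
    return BipartiteNetwork(
        tuple(df.index[row_keep]), tuple(df.columns[col_keep]), mat[np.ix_(row_keep, col_keep)]
    )


def write_incidence_matrix(net: BipartiteNetwork, path: str | Path) -> None:
    pd.DataFrame(net.incidence, index=list(net.plant_labels), columns=list(net.animal_labels)).to_csv(path)


def read_edge_list(path: str | Path, sep: str | None = None) -> DirectedNetwork:
    """Read ordered source,target pairs as a binary directed network.

    A header row (``source,target``) is optional; duplicate pairs collapse
    to one edge; self-pairs are an error.
    """
    df = pd.read_csv(path, header=None, sep=sep, engine="python", dtype=str, skipinitialspace=True)
    if df.shape[1] != 2:
        raise NetworkFormatError(f"{path}: edge list must have exactly two columns")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first in (["source", "target"], ["from", "to"], ["resource", "consumer"]):
        df = df.iloc[1:]
    if df.empty:
        raise NetworkFormatError(f"{path}: empty edge list")
    pairs = [(str(s).strip(), str(t).strip()) for s, t in df.itertuples(index=False)]
    for row, (s, t) in enumerate(pairs, start=1):
        if s == t:
            raise NetworkFormatError(f"{path} row {row}: self-pair {s!r}->{t!r}")
    labels: list[str] = []
    index: dict[str, int] = {}
    for s, t in pairs:
        for name in (s, t):
            if name not in index:
                index[name] = len(labels)
                labels.append(name)
    adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for s, t in pairs:
        adj[index[s], index[t]] = 1
    return DirectedNetwork(tuple(labels), adj)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    rows, cols = np.nonzero(net.adjacency)
    pd.DataFrame(
        {"source": [net.node_labels[i] for i in rows], "target": [net.node_labels[j] for j in cols]}
    ).to_csv(path, index=False)


def foodweb_to_bipartite(net: DirectedNetwork) -> BipartiteNetwork:
    """View a food web as a resource x consumer bipartite incidence matrix.

    Rows are species with at least one outgoing (consumed-by) edge, columns
    species with at least one incoming edge; a species may appear on both
    sides.  The link count is conserved exactly.
    """
    if net.n_edges == 0:
        raise NetworkFormatError("food web has no edges")
    out_deg = net.out_degrees
    in_deg = net.in_degrees
    rows = np.nonzero(out_deg > 0)[0]
    cols = np.nonzero(in_deg > 0)[0]
    incidence = net.adjacency[np.ix_(rows, cols)]
    return BipartiteNetwork(
        tuple(net.node_labels[i] for i in rows),
        tuple(net.node_labels[j] for j in cols),
        incidence,
    )


@dataclass
class SiteRecord:
    """One network's standardized metrics plus its site covariates.

    Units follow the climate-layer conventions: ``T_mean`` in 0.1 degC,
    ``T_seasonality`` as a standard deviation, ``P_ann`` in mm,
    ``P_seasonality`` as a coefficient of variation, ``human_impact`` the
    0-100 human-footprint score, velocities stored raw (log-transformed
    only at analysis time).
    """

    network_id: str
    network_kind: str
    binary: bool
    Z_NODF: float
    Z_M: float
    n_species: int
    n_links: int
    longitude: float
    latitude: float
    elevation: float
    T_mean: float
    T_seasonality: float
    P_ann: float
    P_seasonality: float
    human_impact: float
    T_velocity: float
    P_velocity: float
    n_plants: int | None = None
    n_animals: int | None = None
    mainland_island: str | None = None

    def validate(self) -> None:
        if self.network_kind not in NETWORK_KINDS:
            raise ValueError(f"network_kind must be one of {NETWORK_KINDS}, got {self.network_kind!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not 0.0 <= self.human_impact <= 100.0:
            raise ValueError(f"human_impact {self.human_impact} outside [0, 100]")
        if self.n_links < 1:
            raise ValueError(f"n_links must be >= 1, got {self.n_links}")
        if self.n_species < 1:
            raise ValueError(f"n_species must be positive, got {self.n_species}")
        if self.T_velocity < 0 or self.P_velocity < 0:
            raise ValueError("velocities must be nonnegative")


def _records_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    cols = list(SITE_COLUMNS)
    have_bip = any(r.n_plants is not None for r in records)
    if have_bip:
        cols += ["n_plants", "n_animals"]
    if any(r.mainland_island is not None for r in records):
        cols.append("mainland_island")
    data = {c: [getattr(r, c) for r in records] for c in cols}
    return pd.DataFrame(data)


def write_site_table(records: Sequence[SiteRecord], path: str | Path) -> None:
    """Write site records as CSV with the supplementary-table column schema."""
    _records_to_frame(list(records)).to_csv(path, index=False)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read and validate a site-metadata CSV; invalid rows raise row-indexed errors.

    ``n_species`` may be omitted for bipartite tables when ``n_plants`` and
    ``n_animals`` are present; it is then derived as their sum.
    """
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns and c != "n_species"]
    if missing:
        raise NetworkFormatError(f"{path}: missing mandatory columns {missing}")
    has_n_species = "n_species" in df.columns
    has_parts = "n_plants" in df.columns and "n_animals" in df.columns
    if not has_n_species and not has_parts:
        raise NetworkFormatError(f"{path}: need n_species or n_plants + n_animals")
    records: list[SiteRecord] = []
    for idx, row in df.iterrows():
        if has_n_species and not pd.isna(row.get("n_species")):
            n_species = int(row["n_species"])
        else:
            n_species = int(row["n_plants"]) + int(row["n_animals"])
        rec = SiteRecord(
            network_id=str(row["network_id"]),
            network_kind=str(row["network_kind"]),
            binary=bool(row["binary"]),
            Z_NODF=float(row["Z_NODF"]),
            Z_M=float(row["Z_M"]),
            n_species=n_species,
            n_links=int(row["n_links"]),
            longitude=float(row["longitude"]),
            latitude=float(row["latitude"]),
            elevation=float(row["elevation"]),
            T_mean=float(row["T_mean"]),
            T_seasonality=float(row["T_seasonality"]),
            P_ann=float(row["P_ann"]),
            P_seasonality=float(row["P_seasonality"]),
            human_impact=float(row["human_impact"]),
            T_velocity=float(row["T_velocity"]),
            P_velocity=float(row["P_velocity"]),
            n_plants=None if "n_plants" not in df.columns or pd.isna(row.get("n_plants")) else int(row["n_plants"]),
            n_animals=None if "n_animals" not in df.columns or pd.isna(row.get("n_animals")) else int(row["n_animals"]),
            mainland_island=None
            if "mainland_island" not in df.columns or pd.isna(row.get("mainland_island"))
            else str(row["mainland_island"]),
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise NetworkFormatError(f"{path} row {idx}: {exc}") from exc
        records.append(rec)
    return records


def jaccard_index(n_shared: int, n_union: int) -> float:
    """Jaccard similarity |A & B| / |A | B| between two network datasets."""
    if n_union <= 0 or n_shared < 0 or n_shared > n_union:
        raise ValueError("need 0 <= n_shared <= n_union with n_union > 0")
    return n_shared / n_union


def binary_fraction(n_binary: int, n_total: int) -> float:
    """Fraction (in percent) of networks in a dataset recorded as binary."""
    if n_total <= 0 or not 0 <= n_binary <= n_total:
        raise ValueError("need 0 <= n_binary <= n_total with n_total > 0")
    return 100.0 * n_binary / n_total
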