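"""Domain types and file I/O for areal count data.

The spatial unit of analysis is a small administrative health area (a
"Basic Health Zone" in the motivating setting). Admission counts and
person-years come stratified by 5-year age band x sex; after indirect
standardization the strata are collapsed to one observed/expected pair
per area x condition.

Formats: a plain CSV stratum table, a GAL neighbor-list file for the
adjacency, and (optionally) GeoJSON polygons for map export.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRATUM_COLUMNS = ["area_id", "condition", "stratum_id", "person_years", "count"]


class ArealDataError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric adjacency over an ordered set of area identifiers.

    The order of ``area_ids`` (GAL file order, typically) fixes the row
    order of every matrix downstream, including the CAR precision
    structure.
    """

    area_ids: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self):
        ids = set(self.area_ids)
        if len(ids) != len(self.area_ids):
            raise ArealDataError("duplicate area ids")
        bad_pairs = []
        for a, nbs in self.neighbors.items():
            if a not in ids:
                raise ArealDataError(f"neighbor list for unknown area {a!r}")
            for b in nbs:
                if b not in ids:
                    raise ArealDataError(f"area {a!r} lists unknown neighbor {b!r}")
                if b == a:
                    raise ArealDataError(f"self-loop on area {a!r}")
                if a not in self.neighbors.get(b, frozenset()):
                    bad_pairs.append((a, b))
        if bad_pairs:
            raise ArealDataError(
                "asymmetric adjacency; offending (area, neighbor) pairs: "
                + ", ".join(f"({a},{b})" for a, b in sorted(bad_pairs))
            )
        isolated = [a for a in self.area_ids if not self.neighbors.get(a)]
        if isolated:
            logger.warning("graph has %d isolated area(s): %s", len(isolated),
                           ", ".join(isolated[:10]))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as index pairs (i < k), each listed once."""
        idx = self.index
        out = []
        for a in self.area_ids:
            i = idx[a]
            for b in self.neighbors.get(a, frozenset()):
                k = idx[b]
                if i < k:
                    out.append((i, k))
        return sorted(out)

    def isolated_areas(self) -> list[str]:
        return [a for a in self.area_ids if not self.neighbors.get(a)]

    def adjacency_matrix(self):
        """Binary symmetric adjacency as a scipy.sparse CSR matrix."""
        from scipy import sparse

        rows, cols = [], []
        for i, k in self.edges():
            rows += [i, k]
            cols += [k, i]
        n = self.n_areas
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def connected_components(self) -> list[list[int]]:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        return [sorted(c) for c in nx.connected_components(g)]


@dataclass(frozen=True)
class StratumTable:
    """Long-format counts: one row per (area, condition, age-sex stratum)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        missing = [c for c in STRATUM_COLUMNS if c not in df.columns]
        if missing:
            raise ArealDataError(f"stratum table missing columns: {missing}")
        if (df["person_years"] < 0).any():
            row = df.index[df["person_years"] < 0][0]
            raise ArealDataError(f"negative person_years at row {row}")
        if (df["count"] < 0).any():
            row = df.index[df["count"] < 0][0]
            raise ArealDataError(f"negative count at row {row}")
        if ((df["person_years"] == 0) & (df["count"] > 0)).any():
            row = df.index[(df["person_years"] == 0) & (df["count"] > 0)][0]
            raise ArealDataError(f"count > 0 with zero person_years at row {row}")
        dup = df.duplicated(subset=["area_id", "condition", "stratum_id"])
        if dup.any():
            key = tuple(df.loc[df.index[dup][0], ["area_id", "condition", "stratum_id"]])
            raise ArealDataError(f"duplicate (area_id, condition, stratum_id) key {key}")

    @property
    def area_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["area_id"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StratumTable):
            return NotImplemented
        a = self.frame[STRATUM_COLUMNS].reset_index(drop=True)
        b = other.frame[STRATUM_COLUMNS].reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class AreaConditionData:
    """Collapsed area x condition counts with indirectly standardized expecteds.

    ``observed[i, j]`` and ``expected[i, j]`` follow the row order of
    ``graph.area_ids`` and the column order of ``conditions``. Indirect
    standardization guarantees the per-condition conservation
    ``sum_i expected[i, j] == sum_i observed[i, j]``.
    """

    graph: AreaGraph
    conditions: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    person_years: np.ndarray

    def __post_init__(self):
        n, j = self.graph.n_areas, len(self.conditions)
        if self.observed.shape != (n, j) or self.expected.shape != (n, j):
            raise ArealDataError(
                f"matrix shapes {self.observed.shape}/{self.expected.shape} "
                f"inconsistent with {n} areas x {j} conditions"
            )
        if self.person_years.shape != (n,):
            raise ArealDataError("person_years length mismatch")
        if (self.observed < 0).any():
            raise ArealDataError("negative observed count")
        if (self.expected <= 0).any():
            raise ArealDataError("non-positive expected count")
        o, e = self.observed.sum(axis=0), self.expected.sum(axis=0)
        rel = np.abs(e - o) / np.maximum(o, 1.0)
        if (rel > 1e-6).any():
            j_bad = self.conditions[int(np.argmax(rel))]
            raise ArealDataError(
                f"expected counts do not conserve observed totals for {j_bad!r}"
            )

    @property
    def n_areas(self) -> int:
        return self.graph.n_areas

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def shr(self) -> np.ndarray:
        """Standardized hospitalization ratios O_ij / e_ij."""
        return self.observed / self.expected

    def condition_slice(self, condition: str) -> "AreaConditionData":
        """Single-condition view (for per-condition BYM fits)."""
        j = self.conditions.index(condition)
        return AreaConditionData(
            graph=self.graph,
            conditions=(condition,),
            observed=self.observed[:, [j]],
            expected=self.expected[:, [j]],
            person_years=self.person_years,
        )


# ---------------------------------------------------------------------------
# CSV stratum table I/O


def read_stratum_table(path) -> StratumTable:
    """Read a long-format stratum CSV (header required, UTF-8).

    Unknown columns are ignored; row order is preserved.
    """
    df = pd.read_csv(path, dtype={"area_id": str, "condition": str, "stratum_id": str})
    missing = [c for c in STRATUM_COLUMNS if c not in df.columns]
    if missing:
        raise ArealDataError(f"{path}: missing columns {missing}")
    df = df[STRATUM_COLUMNS].copy()
    if not np.issubdtype(df["count"].dtype, np.integer):
        frac = df["count"] % 1
        if (frac != 0).any():
            row = df.index[frac != 0][0]
            raise ArealDataError(f"{path}: non-integer count at row {row}")
        df["count"] = df["count"].astype(np.int64)
    return StratumTable(df)


def write_stratum_table(table: StratumTable, path) -> None:
    table.frame[STRATUM_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GAL adjacency I/O


def read_adjacency_gal(path) -> AreaGraph:
    """Read a GAL neighbor-list file.

    The header line carries the area count (either ``n`` alone or the
    four-token ``0 n shapefile key`` variant). Then for each area: a line
    ``id n_neighbors`` followed by a line of neighbor ids. Symmetry is
    validated, not repaired.
    """
    with open(path, encoding="utf-8") as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip() and not ln.startswith("!")]
    if not tokens_lines:
        raise ArealDataError(f"{path}: empty GAL file")
    header = tokens_lines[0]
    if len(header) == 1:
        n_declared = int(header[0])
    elif len(header) >= 2:
        n_declared = int(header[1])
    else:  # pragma: no cover - unreachable
        raise ArealDataError(f"{path}: unreadable GAL header")

    flat = [t for line in tokens_lines[1:] for t in line]
    area_ids: list[str] = []
    neighbors: dict[str, frozenset[str]] = {}
    pos = 0
    while pos < len(flat):
        if pos + 1 >= len(flat):
            raise ArealDataError(f"{path}: truncated record near token {pos}")
        aid, k = flat[pos], flat[pos + 1]
        try:
            k = int(k)
        except ValueError:
            raise ArealDataError(f"{path}: bad neighbor count {k!r} for area {aid!r}")
        nbs = flat[pos + 2 : pos + 2 + k]
        if len(nbs) != k:
            raise ArealDataError(f"{path}: truncated neighbor list for area {aid!r}")
        if aid in neighbors:
            raise ArealDataError(f"{path}: duplicate record for area {aid!r}")
        area_ids.append(aid)
        neighbors[aid] = frozenset(nbs)
        pos += 2 + k
    if len(area_ids) != n_declared:
        raise ArealDataError(
            f"{path}: header declares {n_declared} areas, file has {len(area_ids)}"
        )
    return AreaGraph(tuple(area_ids), neighbors)


def write_adjacency_gal(graph: AreaGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{graph.n_areas}\n")
        for a in graph.area_ids:
            nbs = sorted(graph.neighbors.get(a, frozenset()))
            fh.write(f"{a} {len(nbs)}\n")
            fh.write(" ".join(nbs) + "\n" if nbs else "\n")


# ---------------------------------------------------------------------------
# GeoJSON polygons (optional, map export)


def read_geojson_ids(path, id_property: str = "area_id") -> list[str]:
    """Area ids found in a GeoJSON FeatureCollection, in feature order."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    try:
        return [str(f["properties"][id_property]) for f in gj["features"]]
    except KeyError as exc:
        raise ArealDataError(f"{path}: feature missing property {exc}") from exc


def merge_geojson_properties(path_in, path_out, values: pd.DataFrame,
                             id_property: str = "area_id") -> None:
    """Merge per-area columns of ``values`` (indexed by area id) into
    each feature's properties and write the result."""
    with open(path_in, encoding="utf-8") as fh:
        gj = json.load(fh)
    for f in gj["features"]:
        aid = str(f["properties"].get(id_property))
        if aid in values.index:
            for col in values.columns:
                v = values.loc[aid, col]
                f["properties"][col] = v.item() if hasattr(v, "item") else v
    with open(path_out, "w", encoding="utf-8") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# Indirect standardization


def assemble(table: StratumTable, graph: AreaGraph,
             conditions: list[str] | None = None) -> AreaConditionData:
    """Collapse strata to area x condition counts with expected counts by
    indirect standardization.

    Expected counts apply the whole-region stratum-specific rate
    ``r_sj = (sum_i count_isj) / (sum_i n_is)`` to each area's stratum
    person-years: ``e_ij = sum_s n_is * r_sj``. By construction the
    expecteds conserve the observed totals per condition.
    """
    df = table.frame
    t_areas, g_areas = set(df["area_id"]), set(graph.area_ids)
    if t_areas != g_areas:
        only_t = sorted(t_areas - g_areas)[:5]
        only_g = sorted(g_areas - t_areas)[:5]
        raise ArealDataError(
            f"area mismatch between table and graph; only in table: {only_t}, "
            f"only in graph: {only_g}"
        )
    if conditions is None:
        conditions = table.conditions

    # area x stratum person-years (shared across conditions; strata with no
    # row for an area count as zero population)
    py = (df.drop_duplicates(subset=["area_id", "stratum_id"])
            .pivot(index="area_id", columns="stratum_id", values="person_years")
            .reindex(index=graph.area_ids)
            .fillna(0.0))
    counts = (df.pivot_table(index="area_id", columns=["condition", "stratum_id"],
                             values="count", aggfunc="sum", fill_value=0)
                .reindex(index=graph.area_ids, fill_value=0))

    n_is = py.to_numpy(float)                      # N x S
    region_py = n_is.sum(axis=0)                   # S
    observed = np.zeros((graph.n_areas, len(conditions)), dtype=np.int64)
    expected = np.zeros((graph.n_areas, len(conditions)))
    for j, cond in enumerate(conditions):
        if cond in counts.columns.get_level_values(0):
            c = counts[cond].reindex(columns=py.columns, fill_value=0).to_numpy(float)
        else:
            c = np.zeros_like(n_is)
        region_counts = c.sum(axis=0)              # S
        with np.errstate(divide="ignore", invalid="ignore"):
            r_sj = np.where(region_py > 0, region_counts / np.maximum(region_py, 1e-300), 0.0)
        if ((region_py == 0) & (region_counts > 0)).any():
            warnings.warn(f"condition {cond!r}: counts in a zero person-year stratum")
        observed[:, j] = c.sum(axis=1).astype(np.int64)
        expected[:, j] = n_is @ r_sj
        if observed[:, j].sum() == 0:
            raise ArealDataError(f"condition {cond!r} has zero admissions region-wide")
    return AreaConditionData(
        graph=graph,
        conditions=tuple(conditions),
        observed=observed,
        expected=expected,
        person_years=n_is.sum(axis=1),
    )
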