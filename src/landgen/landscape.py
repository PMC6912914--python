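"""From elevation to candidate resistance surfaces and landscape distances.

The pipeline is: elevation raster -> terrain ruggedness index (TRI) ->
coarse aggregation -> monomolecular resistance transform -> pairwise
least-cost or commute distances between sites on a 4-neighbour grid
graph, plus great-circle geographic distances.

TRI follows Wilson et al.: the mean absolute elevation difference to the
(up to 8) neighbouring cells; Riley's root-sum-of-squares variant is
available behind a flag.  Movement is restricted to the four cardinal
directions.  Edge traversal cost is ``cellsize * (r_i + r_j)/2``
(arithmetic mean of cell resistances); commute distances use the
corresponding edge conductance ``(2/(r_i + r_j))/cellsize`` and equal
graph volume x effective resistance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import factorized

from .core import PairwiseMatrix, Raster, SiteSet

__all__ = [
    "TransformSpec",
    "terrain_ruggedness",
    "aggregate",
    "transform_surface",
    "least_cost_distances",
    "commute_distances",
    "geographic_distances",
    "euclidean_cell_distances",
]

FAMILIES = (
    "monomolecular",
    "reverse_monomolecular",
    "inverse_monomolecular",
    "inverse_reverse_monomolecular",
)

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class TransformSpec:
    """Monomolecular resistance transform: family + shape s + magnitude m.

    The input surface is min-max rescaled to x in [0, 1]; the base curve
    g(x) = (1 - exp(-x/s)) / (1 - exp(-1/s)) rises from 0 to 1 with
    curvature controlled by s (small s = saturating early).  ``reverse``
    flips the input (g(1-x)), ``inverse`` flips the output (m - ...), so
    output always spans [1, m].
    """

    family: str = "monomolecular"
    shape: float = 1.0
    magnitude: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.magnitude < 1:
            raise ValueError("magnitude must be >= 1")

    def curve(self, x: np.ndarray) -> np.ndarray:
        """Resistance for scaled input x in [0, 1]."""
        x = np.asarray(x, dtype=float)
        s, m = self.shape, self.magnitude
        g = lambda t: np.expm1(-t / s) / np.expm1(-1.0 / s)  # noqa: E731
        if self.family == "monomolecular":
            out = 1 + (m - 1) * g(x)
        elif self.family == "reverse_monomolecular":
            out = 1 + (m - 1) * g(1 - x)
        elif self.family == "inverse_monomolecular":
            out = m - (m - 1) * g(x)
        else:  # inverse_reverse_monomolecular
            out = m - (m - 1) * g(1 - x)
        return np.clip(out, 1.0, m)


def terrain_ruggedness(elev: Raster, method: str = "wilson") -> Raster:
    """Terrain ruggedness index.

    ``wilson``: mean |elevation difference| over the valid 8-neighbours
    (edge and nodata-adjacent cells use the neighbours available).
    ``riley``: root of the summed squared differences.
    """
    if elev.nrows < 2 or elev.ncols < 2:
        raise ValueError("raster too small for a neighbourhood statistic")
    v = elev.values
    valid = ~elev.nodata_mask
    acc = np.zeros_like(v)
    cnt = np.zeros_like(v)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in shifts:
        sh_v = np.full_like(v, np.nan)
        sh_ok = np.zeros_like(valid)
        rs = slice(max(dr, 0), v.shape[0] + min(dr, 0))
        rd = slice(max(-dr, 0), v.shape[0] + min(-dr, 0))
        cs = slice(max(dc, 0), v.shape[1] + min(dc, 0))
        cd = slice(max(-dc, 0), v.shape[1] + min(-dc, 0))
        sh_v[rd, cd] = v[rs, cs]
        sh_ok[rd, cd] = valid[rs, cs]
        diff = np.where(sh_ok & valid, v - sh_v, 0.0)
        if method == "wilson":
            acc += np.abs(diff)
        elif method == "riley":
            acc += diff ** 2
        else:
            raise ValueError(f"unknown TRI method {method!r}")
        cnt += sh_ok & valid
    out = np.full_like(v, np.nan)
    has = valid & (cnt > 0)
    if method == "wilson":
        out[has] = acc[has] / cnt[has]
    else:
        out[has] = np.sqrt(acc[has])
    return elev.copy_with(out, nodata_mask=~has)


def aggregate(r: Raster, target_cellsize: float, method: str = "mean") -> Raster:
    """Coarsen a raster to target_cellsize by block mean.

    Blocks use factor = floor(target/cellsize); if the target is not an
    integer multiple, the block-meaned grid is bilinearly resampled onto
    the exact target grid.  Blocks more than 50% masked become nodata.
    """
    if method != "mean":
        raise ValueError("only mean aggregation is supported")
    if target_cellsize <= 0:
        raise ValueError("target cellsize must be positive")
    if target_cellsize < r.cellsize:
        raise ValueError("target cellsize must be >= source cellsize")
    f = int(np.floor(target_cellsize / r.cellsize))
    if f == 1 and np.isclose(target_cellsize, r.cellsize):
        return r.copy_with(r.values.copy())
    nr = r.nrows // f
    nc = r.ncols // f
    if nr < 1 or nc < 1:
        raise ValueError("target cellsize larger than the raster extent")
    v = np.where(r.nodata_mask, 0.0, r.values)[: nr * f, : nc * f]
    ok = (~r.nodata_mask)[: nr * f, : nc * f]
    vsum = v.reshape(nr, f, nc, f).sum(axis=(1, 3))
    osum = ok.reshape(nr, f, nc, f).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        block = vsum / osum
    block_mask = osum <= (f * f) / 2.0
    block[block_mask] = np.nan
    inter_size = r.cellsize * f
    out = Raster(values=block, cellsize=inter_size, origin=r.origin,
                 nodata_mask=block_mask, crs_note=r.crs_note)
    if np.isclose(target_cellsize, inter_size):
        return out
    # bilinear resample onto the exact target grid
    tr = max(1, int(np.floor(nr * inter_size / target_cellsize)))
    tc = max(1, int(np.floor(nc * inter_size / target_cellsize)))
    rows = (np.arange(tr) + 0.5) * target_cellsize / inter_size - 0.5
    cols = (np.arange(tc) + 0.5) * target_cellsize / inter_size - 0.5
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    filled = np.where(block_mask, np.nan, block)
    vals = ndimage.map_coordinates(filled, [grid_r, grid_c], order=1,
                                   mode="nearest")
    mask = ~np.isfinite(vals)
    return Raster(values=vals, cellsize=target_cellsize, origin=r.origin,
                  nodata_mask=mask, crs_note=r.crs_note)


def transform_surface(tri: Raster, spec: TransformSpec) -> Raster:
    """Min-max rescale the surface to [0, 1] and apply the transform."""
    v = tri.values
    valid = ~tri.nodata_mask
    vmin = v[valid].min()
    vmax = v[valid].max()
    if vmax > vmin:
        x = (v - vmin) / (vmax - vmin)
    else:
        x = np.zeros_like(v)
    out = np.full_like(v, np.nan)
    out[valid] = spec.curve(x[valid])
    return tri.copy_with(out)


# ---------------------------------------------------------------------------
# grid graphs

def _grid_graph(res: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """4-neighbour edges over valid cells.

    Returns (node_index grid with -1 off-mask, edge i, edge j, mean
    resistance per edge).
    """
    valid = ~res.nodata_mask
    idx = -np.ones(res.shape, dtype=int)
    idx[valid] = np.arange(valid.sum())
    v = res.values
    ii, jj, rr = [], [], []
    # right neighbours
    ok = valid[:, :-1] & valid[:, 1:]
    ii.append(idx[:, :-1][ok])
    jj.append(idx[:, 1:][ok])
    rr.append((v[:, :-1][ok] + v[:, 1:][ok]) / 2.0)
    # down neighbours
    ok = valid[:-1, :] & valid[1:, :]
    ii.append(idx[:-1, :][ok])
    jj.append(idx[1:, :][ok])
    rr.append((v[:-1, :][ok] + v[1:, :][ok]) / 2.0)
    return idx, np.concatenate(ii), np.concatenate(jj), np.concatenate(rr)


def _site_nodes(res: Raster, sites: SiteSet, idx: np.ndarray) -> np.ndarray:
    cells = sites.snapped_cells
    if cells is None:
        cells = sites.snap_to(res)
    nodes = idx[cells[:, 0], cells[:, 1]]
    if np.any(nodes < 0):
        raise ValueError("a site snapped onto a nodata cell")
    return nodes


def _check_connected(n_nodes: int, ei: np.ndarray, ej: np.ndarray,
                     nodes: np.ndarray, labels: list[str]) -> None:
    g = sparse.coo_matrix((np.ones(len(ei)), (ei, ej)), shape=(n_nodes, n_nodes))
    _, comp = connected_components(g, directed=False)
    site_comp = comp[nodes]
    if len(set(site_comp)) > 1:
        groups: dict[int, list[str]] = {}
        for lab, c in zip(labels, site_comp):
            groups.setdefault(int(c), []).append(lab)
        pair = (groups[sorted(groups)[0]][0], groups[sorted(groups)[1]][0])
        raise ValueError(f"sites are not connected on the valid grid, e.g. "
                         f"pair {pair[0]!r} and {pair[1]!r}")


def least_cost_distances(res: Raster, sites: SiteSet) -> PairwiseMatrix:
    """Least-cost (Dijkstra) distances between snapped sites.

    Traversal cost of a 4-neighbour move is cellsize x the mean of the
    two cell resistances, so on a uniform surface of resistance 1 the
    distance is path length in map units.
    """
    idx, ei, ej, rmean = _grid_graph(res)
    n_nodes = int((idx >= 0).sum())
    nodes = _site_nodes(res, sites, idx)
    _check_connected(n_nodes, ei, ej, nodes, sites.site_ids)
    w = res.cellsize * rmean
    g = sparse.coo_matrix((w, (ei, ej)), shape=(n_nodes, n_nodes)).tocsr()
    d = dijkstra(g, directed=False, indices=nodes)
    vals = d[:, nodes]
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(labels=sites.site_ids, values=vals,
                          metric_name="least_cost")


def commute_distances(res: Raster, sites: SiteSet) -> PairwiseMatrix:
    """Commute distances: graph volume x effective resistance.

    Edge conductance is (2/(r_i + r_j))/cellsize on 4-neighbour edges;
    effective resistances come from sparse solves against the grounded
    graph Laplacian.
    """
    idx, ei, ej, rmean = _grid_graph(res)
    n_nodes = int((idx >= 0).sum())
    nodes = _site_nodes(res, sites, idx)
    _check_connected(n_nodes, ei, ej, nodes, sites.site_ids)
    c = (1.0 / res.cellsize) * (1.0 / rmean)
    rows = np.concatenate([ei, ej])
    cols = np.concatenate([ej, ei])
    data = np.concatenate([c, c])
    A = sparse.coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    vol = float(deg.sum())
    L = sparse.diags(deg) - A
    ground = int(nodes[0])
    keep = np.ones(n_nodes, dtype=bool)
    keep[ground] = False
    Lg = L[keep][:, keep].tocsc()
    try:
        solve = factorized(Lg)
    except RuntimeError as exc:  # pragma: no cover
        raise ValueError(f"singular Laplacian solve: {exc}") from exc
    pos = np.cumsum(keep) - 1  # node -> reduced index
    k = len(nodes)
    X = np.zeros((n_nodes, k))
    for s in range(k):
        if nodes[s] == ground:
            continue
        e = np.zeros(n_nodes - 1)
        e[pos[nodes[s]]] = 1.0
        X[keep, s] = solve(e)
    vals = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            na, nb = nodes[a], nodes[b]
            reff = X[na, a] + X[nb, b] - X[nb, a] - X[na, b]
            vals[a, b] = vals[b, a] = vol * reff
    return PairwiseMatrix(labels=sites.site_ids, values=vals,
                          metric_name="commute")


def geographic_distances(sites: SiteSet) -> PairwiseMatrix:
    """Great-circle (haversine) distances in km."""
    if sites.lonlat is None:
        raise ValueError("sites carry no lon/lat coordinates")
    lon = np.radians(sites.lonlat[:, 0])
    lat = np.radians(sites.lonlat[:, 1])
    if np.any(np.abs(sites.lonlat[:, 1]) > 90) or np.any(np.abs(sites.lonlat[:, 0]) > 360):
        raise ValueError("invalid coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(labels=sites.site_ids, values=d,
                          metric_name="geographic")


def euclidean_cell_distances(res: Raster, sites: SiteSet) -> PairwiseMatrix:
    """Straight-line distances between snapped cell centres, in map units.

    The geographic-distance stand-in for synthetic grids without lon/lat.
    """
    cells = sites.snapped_cells
    if cells is None:
        cells = sites.snap_to(res)
    xy = np.array([res.cell_center(r, c) for r, c in cells])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(labels=sites.site_ids, values=d,
                          metric_name="geographic_euclidean")
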