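"""Core spatial containers shared across the pipeline.

Three light dataclasses carry the study's in-memory state between modules:

* :class:`Raster` — a single-band grid (elevation, terrain ruggedness,
  resistance) with square cells, a top-left origin and an explicit nodata
  mask.  Serialized as ESRI ASCII grid (``.asc``), a plain-text raster
  format readable by every GIS.
* :class:`SiteSet` — sampled populations with optional lon/lat and/or
  grid positions, snapped onto raster cells before graph construction.
* :class:`PairwiseMatrix` — a labelled symmetric site-by-site matrix with
  zero diagonal (genetic differentiation or a landscape distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Raster", "SiteSet", "PairwiseMatrix"]

_SYM_TOL = 1e-12


@dataclass
class Raster:
    """Single-band raster with square cells.

    Rows are indexed top to bottom, columns left to right (0-based).  The
    cell center of ``(row, col)`` sits at
    ``origin + ((col + 0.5) * cellsize, -(row + 0.5) * cellsize)``.
    """

    values: np.ndarray
    cellsize: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_note: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cellsize, y0 - (row + 0.5) * self.cellsize)

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Raster":
        return Raster(
            values=np.array(values, dtype=float),
            cellsize=self.cellsize,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            crs_note=self.crs_note,
        )

    # -- ESRI ASCII grid I/O -------------------------------------------------

    def write_asc(self, path: str, nodata_value: float = -9999.0) -> None:
        vals = self.values.copy()
        vals[self.nodata_mask] = nodata_value
        x0, y0 = self.origin
        yll = y0 - self.nrows * self.cellsize
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {x0!r}\n")
            fh.write(f"yllcorner {yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {nodata_value!r}\n")
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_asc(cls, path: str) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        vals = np.loadtxt(lines[n_header:])
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", -9999.0)
        mask = vals == nodata
        vals = vals.astype(float)
        vals[mask] = np.nan
        cellsize = header["cellsize"]
        x0 = header.get("xllcorner", 0.0)
        y0 = header.get("yllcorner", 0.0) + vals.shape[0] * cellsize
        return cls(values=vals, cellsize=cellsize, origin=(x0, y0), nodata_mask=mask)


@dataclass
class SiteSet:
    """Sampling sites with optional geographic and/or grid coordinates."""

    site_ids: list[str]
    lonlat: np.ndarray | None = None      # (n, 2) columns lon, lat
    rowcol: np.ndarray | None = None      # (n, 2) integer row, col
    snapped_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        n = len(self.site_ids)
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site ids")
        if self.lonlat is not None:
            self.lonlat = np.asarray(self.lonlat, dtype=float)
            if self.lonlat.shape != (n, 2):
                raise ValueError("lonlat must be (n_sites, 2)")
        if self.rowcol is not None:
            self.rowcol = np.asarray(self.rowcol, dtype=int)
            if self.rowcol.shape != (n, 2):
                raise ValueError("rowcol must be (n_sites, 2)")
        if self.lonlat is None and self.rowcol is None:
            raise ValueError("need lonlat or rowcol positions")

    def __len__(self) -> int:
        return len(self.site_ids)

    def snap_to(self, raster: Raster) -> np.ndarray:
        """Snap each site to the nearest valid cell; returns (n, 2) row/col.

        Sites with grid positions are snapped to the nearest unmasked cell;
        lon/lat sites are mapped through the raster origin/cellsize (treated
        as projected coordinates).  Two sites landing in the same cell is an
        error — at coarse resolution that makes the pairwise graph singular.
        """
        n = len(self)
        if self.rowcol is not None:
            rc = self.rowcol.astype(float)
        else:
            x0, y0 = raster.origin
            col = (self.lonlat[:, 0] - x0) / raster.cellsize - 0.5
            row = (y0 - self.lonlat[:, 1]) / raster.cellsize - 0.5
            rc = np.column_stack([row, col])
        valid = np.argwhere(~raster.nodata_mask)
        if valid.size == 0:
            raise ValueError("raster has no valid cells")
        snapped = np.empty((n, 2), dtype=int)
        for k in range(n):
            d2 = ((valid - rc[k]) ** 2).sum(axis=1)
            snapped[k] = valid[int(np.argmin(d2))]
        key = snapped[:, 0] * raster.ncols + snapped[:, 1]
        if len(np.unique(key)) != n:
            raise ValueError("two sites snapped to the same raster cell")
        self.snapped_cells = snapped
        return snapped

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame({"site_id": self.site_ids})
        if self.lonlat is not None:
            df["longitude"] = self.lonlat[:, 0]
            df["latitude"] = self.lonlat[:, 1]
        if self.rowcol is not None:
            df["row"] = self.rowcol[:, 0]
            df["col"] = self.rowcol[:, 1]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SiteSet":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        ids = df[cols.get("site_id", df.columns[0])].astype(str).tolist()
        lonlat = None
        rowcol = None
        if "longitude" in cols and "latitude" in cols:
            lonlat = df[[cols["longitude"], cols["latitude"]]].to_numpy(float)
        elif "lon" in cols and "lat" in cols:
            lonlat = df[[cols["lon"], cols["lat"]]].to_numpy(float)
        if "row" in cols and "col" in cols:
            rowcol = df[[cols["row"], cols["col"]]].to_numpy(int)
        return cls(site_ids=ids, lonlat=lonlat, rowcol=rowcol)


@dataclass
class PairwiseMatrix:
    """Symmetric site-by-site matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYM_TOL):
            raise ValueError("diagonal is not zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")
        # exact symmetry for downstream linear algebra
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle pairs as (i_idx, j_idx, values), i < j."""
        iu, ju = np.triu_indices(self.n, k=1)
        return iu, ju, self.values[iu, ju]

    def subset(self, keep: list[str] | np.ndarray) -> "PairwiseMatrix":
        if np.issubdtype(np.asarray(keep).dtype, np.integer):
            idx = np.asarray(keep, dtype=int)
        else:
            pos = {lab: i for i, lab in enumerate(self.labels)}
            idx = np.array([pos[str(k)] for k in keep], dtype=int)
        return PairwiseMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            metric_name=self.metric_name,
            meta=dict(self.meta),
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str, metric_name: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float),
                   metric_name=metric_name)
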