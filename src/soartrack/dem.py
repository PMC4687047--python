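"""Digital elevation model support: ESRI ASCII grid I/O and nearest-cell lookup.

Height above ground level (AGL) is GPS altitude minus the terrain
elevation under the fix.  Lookup is nearest-cell without interpolation:
at the grid resolutions used here (tens of metres) the difference from
bilinear interpolation is well below GPS vertical error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DemCoverageError(ValueError):
    """A queried location falls outside the DEM or on a nodata cell."""


@dataclass
class DemGrid:
    """Rectangular elevation grid in geographic coordinates.

    ``elevation`` is stored with row 0 at the *top* (northernmost), as in
    the ESRI ASCII layout; ``xllcorner``/``yllcorner`` name the lower-left
    corner of the lower-left cell.
    """

    xllcorner: float
    yllcorner: float
    cellsize: float
    elevation: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D matrix")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.elevation.shape[0]

    @property
    def ncols(self) -> int:
        return self.elevation.shape[1]

    def elevation_at(self, lon, lat):
        """Terrain elevation (m) at the nearest cell for each lon/lat.

        Raises :class:`DemCoverageError` naming the first offending point
        if any location is outside the grid or hits a nodata cell.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if bad.any():
            i = int(np.argmax(bad))
            raise DemCoverageError(
                f"fix at lon={lon[i]:.6f}, lat={lat[i]:.6f} is outside the DEM extent"
            )
        z = self.elevation[row, col]
        nod = z == self.nodata
        if nod.any():
            i = int(np.argmax(nod))
            raise DemCoverageError(
                f"fix at lon={lon[i]:.6f}, lat={lat[i]:.6f} falls on a DEM nodata cell"
            )
        return z if z.size > 1 else float(z[0])


def read_esri_ascii(path) -> DemGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"{path}: ESRI ASCII header missing {sorted(missing)}")
    elev = np.array(rows, dtype=float)
    if elev.shape != (int(header["nrows"]), int(header["ncols"])):
        elev = elev.reshape(int(header["nrows"]), int(header["ncols"]))
    return DemGrid(
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        elevation=elev,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_esri_ascii(dem: DemGrid, path) -> None:
    """Write a :class:`DemGrid` as an ESRI ASCII grid."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {dem.ncols}\n")
        fh.write(f"nrows {dem.nrows}\n")
        fh.write(f"xllcorner {float(dem.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(dem.yllcorner)!r}\n")
        fh.write(f"cellsize {float(dem.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(dem.nodata)!r}\n")
        for row in dem.elevation:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
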