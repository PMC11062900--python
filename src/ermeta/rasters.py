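"""Plain-text raster I/O and the aligned soil-layer stack.

Rasters are stored as ESRI ASCII grids (.asc): a six-line header (ncols,
nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of
values, north row first.  Missing cells are NaN in memory.

A :class:`SoilStack` bundles the (variable x statistic x depth-interval)
layers the upscaling needs — TN, SOC, BD, each with mean/q05/q95 per depth
interval — plus a baseline respiration layer, all on one grid.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid",
           "block_aggregate", "SoilStack"]

VARIABLES = ("TN", "SOC", "BD")
STATISTICS = ("mean", "q05", "q95")


@dataclass
class Raster:
    """A single georeferenced grid; ``data`` is float with NaN for nodata."""

    data: np.ndarray
    cellsize: float = 1000.0
    xll: float = 0.0
    yll: float = 0.0

    @property
    def shape(self):
        return self.data.shape

    def grid_matches(self, other: "Raster") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.cellsize, other.cellsize)
                and np.isclose(self.xll, other.xll)
                and np.isclose(self.yll, other.yll))

    @property
    def cell_area(self) -> float:
        """Cell area in the square of the cellsize unit (m2 for metric grids)."""
        return float(self.cellsize) ** 2


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid file."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_head = 0
    for line in lines:
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in {"ncols", "nrows", "xllcorner",
                                        "yllcorner", "cellsize",
                                        "nodata_value"}:
            header[m.group(1).lower()] = float(m.group(2))
            n_head += 1
        else:
            break
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: ASCII grid header missing {req}")
    data = np.loadtxt(io.StringIO("".join(lines[n_head:])), ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid body does not match header shape")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(np.isclose(data, nodata), np.nan, data)
    return Raster(data=data, cellsize=header["cellsize"],
                  xll=header.get("xllcorner", 0.0),
                  yll=header.get("yllcorner", 0.0))


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Write a :class:`Raster` as an ESRI ASCII grid."""
    data = np.where(np.isnan(raster.data), nodata, raster.data)
    nrows, ncols = data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {raster.xll!r}\nyllcorner {raster.yll!r}\n"
                 f"cellsize {raster.cellsize!r}\nNODATA_value {nodata!r}\n")
        np.savetxt(fh, data, fmt="%.10g")


def block_aggregate(raster: Raster, factor: int) -> Raster:
    """Block-mean aggregation to a coarser grid, ignoring missing cells.

    The grid shape must be divisible by ``factor``; blocks that are entirely
    missing stay missing.
    """
    nrows, ncols = raster.shape
    if nrows % factor or ncols % factor:
        raise ValueError(f"grid {raster.shape} not divisible by factor {factor}")
    blocks = raster.data.reshape(nrows // factor, factor,
                                 ncols // factor, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks.transpose(0, 2, 1, 3)
                         .reshape(nrows // factor, ncols // factor, -1), axis=2)
    return Raster(out, cellsize=raster.cellsize * factor,
                  xll=raster.xll, yll=raster.yll)


def _layer_name(var: str, stat: str, interval) -> str:
    top, bottom = interval
    return f"{var}_{stat}_{top:g}-{bottom:g}cm"


@dataclass
class SoilStack:
    """Aligned stack of soil layers on one grid.

    ``layers`` maps (variable, statistic, (top_cm, bottom_cm)) to a
    :class:`Raster`; ``baseline_er`` (gC m-2 yr-1) is optional.  All layers
    must share grid geometry; cells with q05 > q95 in any layer pair are
    masked across the stack (counted in ``n_masked_percentile``).
    """

    layers: dict
    baseline_er: Raster | None = None
    n_masked_percentile: int = 0
    intervals: list = field(default_factory=list)

    def __post_init__(self):
        rasters = list(self.layers.values())
        if not rasters:
            raise ValueError("empty soil stack")
        ref = rasters[0]
        for key, r in self.layers.items():
            if not r.grid_matches(ref):
                raise ValueError(f"layer {key} does not share the stack grid")
        if self.baseline_er is not None and not self.baseline_er.grid_matches(ref):
            raise ValueError("baseline_er does not share the stack grid")
        self.intervals = sorted({key[2] for key in self.layers})
        # mandatory-layer completeness + percentile sanity masking
        invalid = np.zeros(ref.shape, dtype=bool)
        missing = np.zeros(ref.shape, dtype=bool)
        for var in VARIABLES:
            for interval in self.intervals:
                for stat in STATISTICS:
                    key = (var, stat, interval)
                    if key not in self.layers:
                        raise ValueError(f"missing mandatory layer {key}")
                    missing |= np.isnan(self.layers[key].data)
                lo = self.layers[(var, "q05", interval)].data
                hi = self.layers[(var, "q95", interval)].data
                invalid |= lo > hi
        self.n_masked_percentile = int(np.sum(invalid & ~missing))
        mask = invalid | missing
        if mask.any():
            for r in self.layers.values():
                r.data[mask] = np.nan

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    def array(self, var: str, stat: str, interval) -> np.ndarray:
        return self.layers[(var, stat, interval)].data

    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.array("TN", "mean", self.intervals[0]))))

    def aggregate(self, factor: int) -> "SoilStack":
        """Block-mean aggregate every layer (and baseline) by ``factor``."""
        layers = {k: block_aggregate(r, factor) for k, r in self.layers.items()}
        base = (block_aggregate(self.baseline_er, factor)
                if self.baseline_er is not None else None)
        return SoilStack(layers=layers, baseline_er=base)

    # -- disk round trip ---------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (var, stat, interval), r in self.layers.items():
            write_ascii_grid(r, directory / f"{_layer_name(var, stat, interval)}.asc")
        if self.baseline_er is not None:
            write_ascii_grid(self.baseline_er, directory / "baseline_er.asc")

    @classmethod
    def load(cls, directory) -> "SoilStack":
        directory = Path(directory)
        pat = re.compile(
            r"^(TN|SOC|BD)_(mean|q05|q95)_([0-9.]+)-([0-9.]+)cm\.asc$")
        layers = {}
        for f in sorted(directory.glob("*.asc")):
            m = pat.match(f.name)
            if m:
                key = (m.group(1), m.group(2),
                       (float(m.group(3)), float(m.group(4))))
                layers[key] = read_ascii_grid(f)
        base_path = directory / "baseline_er.asc"
        base = read_ascii_grid(base_path) if base_path.exists() else None
        if not layers:
            raise ValueError(f"no soil layers found in {directory}")
        return cls(layers=layers, baseline_er=base)
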