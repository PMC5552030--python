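"""Raster ingestion, validation, and tabular/CSV serialization.

A landscape is an aligned pair of single-band rasters at a common (default
3 m) resolution: a digital terrain model (ground elevation) and a
categorical land-cover map.  On read the elevation band is converted once
from its vertical datum to meters above MLHW (``raw - datum_offset_mlhw``);
all downstream code works in MLHW meters.

GeoTIFF I/O uses :mod:`tifffile`.  The affine transform and CRS are carried
opaquely in a JSON ``ImageDescription`` tag (plus the GDAL nodata tag) and
are never used in computation; model distances come from cell centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .communities import COMMUNITIES, NODATA, WATER
from .errors import AlignmentError, SchemaError

#: Identity affine transform (GDAL order: x0, dx, 0, y0, 0, dy).
IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)

_GDAL_NODATA_TAG = 42113


@dataclass
class LandscapeGrid:
    """Aligned elevation + community rasters with datum metadata.

    ``elevation`` is in meters above MLHW (datum conversion happens at
    ingestion).  ``community`` holds string codes: the nine community codes
    plus the ``WATER`` and ``NODATA`` sentinels.
    """

    elevation: np.ndarray
    community: np.ndarray
    cell_size: float = 3.0
    datum_offset_mlhw: float = 0.0
    transform: tuple = IDENTITY_TRANSFORM
    crs: str = ""
    classes: tuple[str, ...] = COMMUNITIES

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.community = np.asarray(self.community, dtype="U16")
        self.validate()

    def validate(self) -> None:
        if self.elevation.shape != self.community.shape:
            raise AlignmentError(
                f"elevation shape {self.elevation.shape} != "
                f"community shape {self.community.shape}"
            )
        if not self.cell_size > 0:
            raise SchemaError("cell_size must be positive")
        allowed = set(self.classes) | {WATER, NODATA}
        codes = set(np.unique(self.community))
        unknown = codes - allowed
        if unknown:
            raise SchemaError(f"unknown community codes: {sorted(unknown)}")
        is_comm = np.isin(self.community, list(self.classes))
        if not np.all(np.isfinite(self.elevation[is_comm])):
            raise SchemaError("non-finite elevation under a community cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


def _write_band(path, data, description: dict, nodata):
    extratags = [(_GDAL_NODATA_TAG, "s", 0, str(nodata), True)]
    tifffile.imwrite(
        path, data, description=json.dumps(description), extratags=extratags
    )


def _read_band(path):
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise SchemaError(f"{path}: expected a single-band raster")
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except (TypeError, ValueError):
                desc = {}
        nodata = None
        tag = page.tags.get(_GDAL_NODATA_TAG)
        if tag is not None:
            nodata = float(tag.value)
    return data, desc, nodata


def write_landscape(grid: LandscapeGrid, dtm_path, landcover_path) -> None:
    """Write the grid as a GeoTIFF pair readable by :func:`read_landscape`.

    The elevation band is stored in the raster's native datum
    (``elevation_mlhw + datum_offset_mlhw``) at full float64 precision, so
    a read with the same offset round-trips exactly.
    """
    meta = {
        "transform": list(grid.transform),
        "crs": grid.crs,
        "cell_size": grid.cell_size,
    }
    raw = grid.elevation + grid.datum_offset_mlhw
    _write_band(dtm_path, raw.astype(np.float64), meta, nodata=np.nan)

    labels = [NODATA, WATER] + list(grid.classes)
    code_of = {lab: i - 1 for i, lab in enumerate(labels)}  # NODATA -> -1
    codes = np.vectorize(code_of.__getitem__, otypes=[np.int16])(grid.community)
    meta_lc = dict(meta)
    meta_lc["code_map"] = {lab: code_of[lab] for lab in labels}
    _write_band(landcover_path, codes, meta_lc, nodata=-1)


def read_landscape(
    dtm_path,
    landcover_path,
    datum_offset_mlhw: float = 0.0,
    classes: tuple[str, ...] = COMMUNITIES,
    code_map: Mapping[int, str] | None = None,
    cell_size: float | None = None,
) -> LandscapeGrid:
    """Read an aligned DTM + land-cover GeoTIFF pair.

    Parameters
    ----------
    datum_offset_mlhw
        Elevation of MLHW in the DTM's vertical datum (m); subtracted from
        the raw band so the returned grid is in meters above MLHW.
    code_map
        Optional integer-code -> community-code mapping.  This is also where
        a many-to-one grouping of raw land-cover classes into the modeled
        communities is expressed.  Defaults to the map embedded in the
        land-cover raster's metadata.
    """
    elev, meta_e, _ = _read_band(dtm_path)
    lc, meta_lc, lc_nodata = _read_band(landcover_path)
    if elev.shape != lc.shape:
        raise AlignmentError(
            f"DTM shape {elev.shape} != land-cover shape {lc.shape}"
        )
    t_e = meta_e.get("transform")
    t_lc = meta_lc.get("transform")
    if t_e is not None and t_lc is not None:
        if not np.allclose(t_e, t_lc, rtol=0, atol=1e-6):
            raise AlignmentError("DTM and land-cover georeference differ")

    if code_map is None:
        embedded = meta_lc.get("code_map")
        if embedded is None:
            raise SchemaError(
                f"{landcover_path}: no code_map metadata and none supplied"
            )
        code_map = {int(v): k for k, v in embedded.items()}
    else:
        code_map = {int(k): v for k, v in code_map.items()}
    if lc_nodata is not None:
        code_map.setdefault(int(lc_nodata), NODATA)

    lc = np.asarray(lc)
    community = np.empty(lc.shape, dtype="U16")
    known = np.zeros(lc.shape, dtype=bool)
    for code, label in code_map.items():
        m = lc == code
        community[m] = label
        known |= m
    if not known.all():
        bad = sorted(np.unique(lc[~known]).tolist())
        raise SchemaError(f"unmapped land-cover codes: {bad}")

    elev = np.asarray(elev, dtype=float) - datum_offset_mlhw
    # nodata elevation under a community cell is dropped to NODATA
    bad_elev = ~np.isfinite(elev) & np.isin(community, list(classes))
    community[bad_elev] = NODATA

    if cell_size is None:
        cell_size = float(meta_e.get("cell_size", 3.0))
    return LandscapeGrid(
        elevation=elev,
        community=community,
        cell_size=cell_size,
        datum_offset_mlhw=datum_offset_mlhw,
        transform=tuple(t_e) if t_e is not None else IDENTITY_TRANSFORM,
        crs=meta_e.get("crs", ""),
        classes=tuple(classes),
    )


def to_pixel_table(grid: LandscapeGrid) -> pd.DataFrame:
    """Flatten a grid to one record per natural-community cell.

    Open-water and nodata cells are excluded.  ``x``/``y`` are cell-center
    coordinates in projected meters (row/col times cell size), the only
    spatial information the models use.
    """
    is_comm = np.isin(grid.community, list(grid.classes))
    rows, cols = np.nonzero(is_comm)
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "x": (cols + 0.5) * grid.cell_size,
            "y": (rows + 0.5) * grid.cell_size,
            "elevation": grid.elevation[rows, cols],
            "community": pd.Categorical(
                grid.community[rows, cols], categories=list(grid.classes)
            ),
        }
    )
    return df


def write_summary_tables(results, initial_counts: pd.Series, out_dir,
                         float_format: str = "%.10g") -> list[Path]:
    """Serialize replicate summaries to a deterministic CSV set.

    ``results`` maps a scenario label (e.g. ``"rise_0.2"``) to a
    ``ReplicateResult`` from :mod:`barrier_slr.simulate`.  Writes, per
    scenario, the mean transition contingency matrix in percent-of-total and
    row-proportion forms, plus pooled proportion-interval and percent-change
    tables.  Column/row order follows the configured community order, so a
    rerun with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    n_total = float(initial_counts.sum())
    communities = list(initial_counts.index)

    rows = []
    for label, res in results.items():
        cont = res.contingency_mean  # DataFrame from x (communities + ABSORBED)
        pct = cont / n_total * 100.0
        p = out_dir / f"contingency_{label}_percent.csv"
        pct.to_csv(p, float_format=float_format)
        written.append(p)

        row_sums = cont.sum(axis=1)
        rowprop = cont.div(row_sums.replace(0.0, np.nan), axis=0).fillna(0.0)
        p = out_dir / f"contingency_{label}_rowprop.csv"
        rowprop.to_csv(p, float_format=float_format)
        written.append(p)

        for basis in ("total", "remaining"):
            s = res.summary(basis)
            for c in communities:
                rows.append(
                    {
                        "scenario": label,
                        "basis": basis,
                        "community": c,
                        "median": s.loc[c, "median"],
                        "lo2.5": s.loc[c, "lo2.5"],
                        "hi97.5": s.loc[c, "hi97.5"],
                        "n_reps": res.n_reps,
                        "absorbed": res.absorbed,
                    }
                )
    intervals = pd.DataFrame(rows)
    p = out_dir / "replicate_intervals.csv"
    intervals.to_csv(p, index=False, float_format=float_format)
    written.append(p)

    initial_p = out_dir / "initial_proportions.csv"
    (initial_counts / n_total).rename("proportion").to_csv(
        initial_p, float_format=float_format
    )
    written.append(initial_p)
    return written
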