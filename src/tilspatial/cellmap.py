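"""Cell maps: per-sample cell tables plus tumor/stroma compartment geometry.

A *cell map* is the atomic analysis unit downstream of any segmentation
front-end: one row per nucleus centroid (micron coordinates), a phenotype
label (lymphocyte / tumor cell / other), and a compartment label (tumor
region vs stroma) derived from tissue and tumor-region polygons.

Conventions
-----------
* Coordinates are micrometers, origin top-left, y increasing downward
  (image convention).  ``microns_per_pixel`` is applied once at ingest.
* Cell tables are CSV (UTF-8, '.' decimal) with columns
  ``cell_id,x,y,phenotype[,compartment]``; phenotype/compartment are
  uppercase strings.
* Compartment geometry is a GeoJSON FeatureCollection in planar micron
  coordinates; each feature carries ``properties.role`` = ``tissue`` or
  ``tumor``.
* Areas are reported in mm².
* A point exactly on a tumor-polygon edge belongs to the tumor region
  (closed polygons) — deterministic, and consistent with how rasterized
  segmentation masks resolve boundary pixels.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union

UM2_PER_MM2 = 1e6

CELL_COLUMNS = ("cell_id", "x", "y", "phenotype", "compartment")
REQUIRED_COLUMNS = ("cell_id", "x", "y", "phenotype")


class Phenotype(str, enum.Enum):
    LYMPHOCYTE = "LYMPHOCYTE"
    TUMOR = "TUMOR"
    OTHER = "OTHER"


class Compartment(str, enum.Enum):
    TUMOR_REGION = "TUMOR_REGION"
    STROMA = "STROMA"


class CellTableFormatError(ValueError):
    """Malformed cell table (missing columns, non-numeric coordinates)."""


class ConfigurationError(ValueError):
    """Inputs insufficient to build a valid cell map."""


class GeometryError(ValueError):
    """Geometry inconsistent with the cells or degenerate."""


class ConsistencyError(ValueError):
    """Provided compartment labels disagree with the geometry."""


@dataclass(frozen=True)
class CompartmentGeometry:
    """Tissue polygon plus tumor-region polygons; areas derived in mm².

    Tumor polygons are clipped to the tissue polygon; the stroma is the
    remainder, so ``stroma_area_mm2 = tissue_area_mm2 - tumor_area_mm2``.
    """

    tissue_polygon: Polygon
    tumor_polygons: tuple = ()

    def __post_init__(self):
        if self.tissue_polygon.is_empty or self.tissue_polygon.area <= 0:
            raise GeometryError("tissue polygon must have positive area")
        object.__setattr__(self, "tumor_polygons", tuple(self.tumor_polygons))

    @property
    def tumor_union(self):
        """Union of tumor polygons clipped to the tissue polygon."""
        if not self.tumor_polygons:
            return Polygon()
        return unary_union(list(self.tumor_polygons)).intersection(self.tissue_polygon)

    @property
    def tissue_area_mm2(self) -> float:
        return self.tissue_polygon.area / UM2_PER_MM2

    @property
    def tumor_area_mm2(self) -> float:
        return self.tumor_union.area / UM2_PER_MM2

    @property
    def stroma_area_mm2(self) -> float:
        return self.tissue_area_mm2 - self.tumor_area_mm2


@dataclass
class CellMap:
    """One sample's cells plus compartment geometry.

    ``cells`` is a DataFrame with columns cell_id (int), x, y (float, μm),
    phenotype and compartment (uppercase strings from the enums).
    """

    sample_id: str
    cells: pd.DataFrame
    geometry: CompartmentGeometry
    microns_per_pixel: float = 1.0

    def validate(self, check_geometry_consistency: bool = True) -> "CellMap":
        df = self.cells
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise CellTableFormatError(f"missing columns: {missing}")
        if len(df) < 1:
            raise CellTableFormatError("cell map must contain at least one cell")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise CellTableFormatError(f"duplicate cell_id {dup!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise CellTableFormatError("non-finite coordinates")
        _check_labels(df["phenotype"], Phenotype, "phenotype")
        _check_labels(df["compartment"], Compartment, "compartment")
        if check_geometry_consistency:
            expected = assign_compartments(xy[:, 0], xy[:, 1], self.geometry)
            got = df["compartment"].to_numpy()
            bad = np.nonzero(expected != got)[0]
            if bad.size:
                i = int(bad[0])
                raise ConsistencyError(
                    f"compartment of cell_id {df['cell_id'].iloc[i]} is "
                    f"{got[i]} but geometry implies {expected[i]} "
                    f"({bad.size} disagreement(s) total)"
                )
        return self

    def coords(self, phenotype: Phenotype | str | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one phenotype."""
        df = self.cells
        if phenotype is not None:
            df = df[df["phenotype"] == _as_value(phenotype, Phenotype)]
        return df[["x", "y"]].to_numpy(dtype=float)

    def subset_ids(self, phenotype: Phenotype | str) -> np.ndarray:
        df = self.cells
        return df.loc[
            df["phenotype"] == _as_value(phenotype, Phenotype), "cell_id"
        ].to_numpy()

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _as_value(label, enum_cls) -> str:
    if isinstance(label, enum_cls):
        return label.value
    return str(label)


def _check_labels(series: pd.Series, enum_cls, name: str) -> None:
    valid = {m.value for m in enum_cls}
    bad = ~series.isin(valid)
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown {name} label {series.iloc[i]!r} at row {i} "
            f"(valid: {sorted(valid)})"
        )


# ---------------------------------------------------------------------------
# Phenotype / compartment assignment rules
# ---------------------------------------------------------------------------

def assign_phenotype(is_lymphocyte: bool, compartment: Compartment | str) -> Phenotype:
    """Integrate lymphocyte classification with the tissue partition.

    Lymphocytes keep their identity irrespective of location (a lymphocyte
    inside a tumor nest is still a lymphocyte); any other nucleus inside
    the tumor region is a tumor cell, and any other nucleus in the stroma
    is an "other" cell (fibroblasts, endothelium, ...).
    """
    if is_lymphocyte:
        return Phenotype.LYMPHOCYTE
    if _as_value(compartment, Compartment) == Compartment.TUMOR_REGION.value:
        return Phenotype.TUMOR
    return Phenotype.OTHER


def assign_compartments(
    x: np.ndarray, y: np.ndarray, geometry: CompartmentGeometry
) -> np.ndarray:
    """Vectorized compartment assignment for point arrays (boundary→tumor)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    in_tissue = shapely.intersects_xy(geometry.tissue_polygon, x, y)
    if not in_tissue.all():
        i = int(np.nonzero(~in_tissue)[0][0])
        raise GeometryError(f"point ({x[i]:.3f}, {y[i]:.3f}) outside tissue polygon")
    tumor = geometry.tumor_union
    if tumor.is_empty:
        in_tumor = np.zeros(x.shape, dtype=bool)
    else:
        in_tumor = shapely.intersects_xy(tumor, x, y)
    out = np.where(in_tumor, Compartment.TUMOR_REGION.value, Compartment.STROMA.value)
    return out


def assign_compartment(cell, geometry: CompartmentGeometry) -> Compartment:
    """Compartment of a single cell (anything exposing .x/.y or a 2-tuple)."""
    if hasattr(cell, "x"):
        x, y = float(cell.x), float(cell.y)
    else:
        x, y = float(cell[0]), float(cell[1])
    value = assign_compartments(np.array([x]), np.array([y]), geometry)[0]
    return Compartment(value)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_geometry(path: str | Path) -> CompartmentGeometry:
    """Read a GeoJSON FeatureCollection with role=tissue|tumor features."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    tissue, tumors = None, []
    for feat in doc.get("features", []):
        role = (feat.get("properties") or {}).get("role")
        geom = shape(feat["geometry"])
        if role == "tissue":
            if tissue is not None:
                raise GeometryError("multiple tissue features in geometry file")
            tissue = geom
        elif role == "tumor":
            tumors.append(geom)
        else:
            raise GeometryError(f"feature with unknown role {role!r}")
    if tissue is None:
        raise GeometryError("geometry file lacks a role=tissue feature")
    return CompartmentGeometry(tissue_polygon=tissue, tumor_polygons=tuple(tumors))


def write_geometry(geometry: CompartmentGeometry, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"role": "tissue"},
            "geometry": mapping(geometry.tissue_polygon),
        }
    ]
    for poly in geometry.tumor_polygons:
        features.append(
            {"type": "Feature", "properties": {"role": "tumor"}, "geometry": mapping(poly)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_cell_table(
    path: str | Path,
    geometry_path: str | Path | None = None,
    sample_id: str | None = None,
    microns_per_pixel: float = 1.0,
) -> CellMap:
    """Read a cells CSV (plus GeoJSON geometry) into a validated CellMap.

    If the table lacks a ``compartment`` column, compartments are assigned
    from the geometry.  If both are present they must agree — disagreement
    surfaces front-end inconsistencies and raises ``ConsistencyError``
    rather than silently overriding.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"{path.name}: missing columns {missing}")
    try:
        df["x"] = pd.to_numeric(df["x"], errors="raise").astype(float)
        df["y"] = pd.to_numeric(df["y"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise CellTableFormatError(f"{path.name}: non-numeric coordinates: {exc}")
    if microns_per_pixel != 1.0:
        df["x"] = df["x"] * microns_per_pixel
        df["y"] = df["y"] * microns_per_pixel
    _check_labels(df["phenotype"], Phenotype, "phenotype")

    geometry = read_geometry(geometry_path) if geometry_path is not None else None
    has_comp = "compartment" in df.columns
    if not has_comp and geometry is None:
        raise ConfigurationError(
            "no geometry file and no compartment column: cannot assign compartments"
        )
    if geometry is None:
        # Areas unknown: synthesize a bounding-box tissue so downstream code
        # that needs only the labels still works; area-based features will be
        # computed against this hull, so callers should prefer real geometry.
        pad = 1.0
        x0, x1 = df["x"].min() - pad, df["x"].max() + pad
        y0, y1 = df["y"].min() - pad, df["y"].max() + pad
        tissue = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        geometry = CompartmentGeometry(tissue_polygon=tissue)
        check_geom = False
    else:
        check_geom = True
        if not has_comp:
            df["compartment"] = assign_compartments(
                df["x"].to_numpy(), df["y"].to_numpy(), geometry
            )
    _check_labels(df["compartment"], Compartment, "compartment")
    cm = CellMap(
        sample_id=sample_id or path.stem,
        cells=df[list(CELL_COLUMNS)].reset_index(drop=True),
        geometry=geometry,
        microns_per_pixel=microns_per_pixel,
    )
    return cm.validate(check_geometry_consistency=check_geom)


def write_cell_table(
    cellmap: CellMap, path: str | Path, geometry_path: str | Path | None = None
) -> None:
    """Write the cells CSV (float coordinates at full repr precision)."""
    df = cellmap.cells[list(CELL_COLUMNS)]
    df.to_csv(path, index=False)
    if geometry_path is not None:
        write_geometry(cellmap.geometry, geometry_path)
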