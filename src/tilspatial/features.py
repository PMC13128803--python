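"""Spatial feature families computed from a cell map.

Three families, mirroring how spatial TIL organization is quantified in
digital pathology:

1. **Bidirectional proximity metrics.**  With either lymphocytes or tumor
   cells as reference, and the other phenotype as target, we record per
   radius r ∈ {10, 20, 30, 50, 100, 200} μm the mean number of targets
   within r of a reference cell (``avg_count_r``), the same normalized by
   the disk area (``avg_density_r``, per mm²), and the mean
   nearest-target distance over reference cells whose nearest target
   lies within r (``avg_min_distance_r``, μm).  The last is a per-cell
   censored mean: a reference cell only contributes when its nearest
   target is ≤ r, which is what makes the per-radius values carry
   distinct information.

2. **Lymphocyte aggregates.**  Clusters of same-phenotype cells linked at
   intercellular distances strictly below 20 μm.  The default linkage is
   single-linkage connected components (cells chained by sub-threshold
   adjacencies form one cluster); a stricter maximal-clique mode (ALL
   pairwise distances sub-threshold) is available.  For each size
   threshold n ∈ {2..5}: number of clusters with ≥ n cells, that count
   per mm² of tissue, and the mean size of qualifying clusters.

3. **Compartment quantification.**  Counts and densities of lymphocytes
   and tumor cells in the tumor region, the stroma, and overall, plus the
   stromal lymphocyte percentage (stromal lymphocytes / all stromal
   cells × 100).

Distances are centroid Euclidean in μm with no edge correction at the
tissue boundary.  Features undefined on a sample (e.g. proximity metrics
when a phenotype is absent) are recorded as missing (NaN), never
zero-filled: imputation is the model's job, not extraction's.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cellmap import UM2_PER_MM2, CellMap, Compartment, GeometryError, Phenotype

DEFAULT_RADII_UM = (10.0, 20.0, 30.0, 50.0, 100.0, 200.0)


class EmptyInputError(ValueError):
    """No reference cells to measure from."""


class LinkageMode(str, enum.Enum):
    SINGLE_LINKAGE = "SINGLE_LINKAGE"
    CLIQUE = "CLIQUE"


@dataclass(frozen=True)
class ProximityConfig:
    radii_um: tuple = DEFAULT_RADII_UM

    def validate(self) -> "ProximityConfig":
        r = np.asarray(self.radii_um, dtype=float)
        if len(r) == 0 or (r <= 0).any() or (np.diff(r) <= 0).any():
            raise ValueError("radii_um must be strictly increasing and > 0")
        return self


@dataclass(frozen=True)
class AggregateConfig:
    link_distance_um: float = 20.0
    size_thresholds: tuple = (2, 3, 4, 5)
    linkage_mode: LinkageMode = LinkageMode.SINGLE_LINKAGE

    def validate(self) -> "AggregateConfig":
        if self.link_distance_um <= 0:
            raise ValueError("link_distance_um must be > 0")
        t = np.asarray(self.size_thresholds, dtype=int)
        if len(t) == 0 or (t < 2).any() or (np.diff(t) <= 0).any():
            raise ValueError("size_thresholds must be increasing integers >= 2")
        return self


# ---------------------------------------------------------------------------
# Proximity metrics
# ---------------------------------------------------------------------------

def nearest_target_distances(
    cellmap: CellMap, reference: Phenotype | str, target: Phenotype | str
) -> np.ndarray:
    """Per-reference-cell Euclidean distance (μm) to the nearest target cell.

    Returns NaN entries when the sample contains no target cells.
    """
    if str(getattr(reference, "value", reference)) == str(
        getattr(target, "value", target)
    ):
        raise ValueError("reference and target phenotypes must differ")
    ref = cellmap.coords(reference)
    if len(ref) == 0:
        raise EmptyInputError(f"no {reference} reference cells in sample")
    tgt = cellmap.coords(target)
    if len(tgt) == 0:
        return np.full(len(ref), np.nan)
    d, _ = cKDTree(tgt).query(ref, k=1)
    return np.asarray(d, dtype=float)


def counts_within_radius(
    cellmap: CellMap,
    reference: Phenotype | str,
    target: Phenotype | str,
    r: float,
) -> np.ndarray:
    """Per-reference-cell count of target cells at distance ≤ r (μm)."""
    if r <= 0:
        raise ValueError("r must be > 0")
    ref = cellmap.coords(reference)
    if len(ref) == 0:
        raise EmptyInputError(f"no {reference} reference cells in sample")
    tgt = cellmap.coords(target)
    if len(tgt) == 0:
        return np.zeros(len(ref), dtype=int)
    counts = cKDTree(tgt).query_ball_point(ref, r, return_length=True)
    return np.asarray(counts, dtype=int)


def average_min_distance(
    cellmap: CellMap,
    reference: Phenotype | str,
    target: Phenotype | str,
    r: float,
) -> float:
    """Mean nearest-target distance over reference cells with nearest ≤ r.

    NaN when no reference cell has its nearest target within r.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    d = nearest_target_distances(cellmap, reference, target)
    qualifying = d[np.isfinite(d) & (d <= r)]
    return float(qualifying.mean()) if qualifying.size else float("nan")


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------

def _subthreshold_pairs(xy: np.ndarray, link_distance: float) -> np.ndarray:
    """(k, 2) index pairs at strictly sub-threshold distance."""
    if len(xy) < 2:
        return np.empty((0, 2), dtype=int)
    pairs = cKDTree(xy).query_pairs(r=link_distance, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
    return pairs[d < link_distance]  # strict '<': exactly-at-threshold pairs drop


def detect_aggregates(
    cellmap: CellMap, phenotype: Phenotype | str, config: AggregateConfig
) -> list[frozenset]:
    """Clusters (sets of cell_ids) of one phenotype under the linkage rule.

    SINGLE_LINKAGE returns the connected components of the sub-threshold
    adjacency graph (singletons included; size thresholds filter later).
    CLIQUE returns all maximal sets whose pairwise distances are all
    sub-threshold; a cell may belong to several maximal cliques.
    """
    config.validate()
    xy = cellmap.coords(phenotype)
    ids = cellmap.subset_ids(phenotype)
    if len(xy) == 0:
        return []
    pairs = _subthreshold_pairs(xy, config.link_distance_um)
    if config.linkage_mode == LinkageMode.SINGLE_LINKAGE:
        n = len(xy)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
            _, labels = connected_components(adj, directed=False)
        else:
            labels = np.arange(n)
        clusters: dict[int, list] = {}
        for idx, lab in enumerate(labels):
            clusters.setdefault(int(lab), []).append(ids[idx])
        return [frozenset(v) for v in clusters.values()]
    # CLIQUE mode
    g = nx.Graph()
    g.add_nodes_from(range(len(xy)))
    g.add_edges_from(map(tuple, pairs))
    return [frozenset(ids[i] for i in clique) for clique in nx.find_cliques(g)]


def aggregate_features(
    clusters: Sequence[frozenset],
    size_thresholds: Iterable[int],
    tissue_area_mm2: float,
) -> dict[str, float]:
    """Aggregate-n counts, densities (per mm² tissue) and mean sizes."""
    if tissue_area_mm2 <= 0:
        raise GeometryError("tissue_area_mm2 must be > 0")
    sizes = np.array([len(c) for c in clusters], dtype=int)
    out: dict[str, float] = {}
    for n in size_thresholds:
        q = sizes[sizes >= n]
        out[f"aggregate_{n}_count"] = float(len(q))
        out[f"aggregate_{n}_density"] = float(len(q) / tissue_area_mm2)
        out[f"aggregate_{n}_mean_cells"] = (
            float(q.mean()) if q.size else float("nan")
        )
    return out


# ---------------------------------------------------------------------------
# Compartment quantification
# ---------------------------------------------------------------------------

def compartment_quantification(cellmap: CellMap) -> dict[str, float]:
    """Counts/densities of lymphocytes and tumor cells per compartment."""
    geom = cellmap.geometry
    if geom.tissue_area_mm2 <= 0:
        raise GeometryError("tissue area must be > 0")
    df = cellmap.cells
    in_tumor = df["compartment"] == Compartment.TUMOR_REGION.value
    in_stroma = ~in_tumor
    areas = {
        "tumor_region": geom.tumor_area_mm2,
        "stroma": geom.stroma_area_mm2,
        "total": geom.tissue_area_mm2,
    }
    masks = {"tumor_region": in_tumor, "stroma": in_stroma,
             "total": pd.Series(True, index=df.index)}
    out: dict[str, float] = {}
    for pheno, tag in ((Phenotype.LYMPHOCYTE, "lym"), (Phenotype.TUMOR, "tumor")):
        is_pheno = df["phenotype"] == pheno.value
        for comp, mask in masks.items():
            count = int((is_pheno & mask).sum())
            area = areas[comp]
            out[f"{tag}_count_{comp}"] = float(count)
            out[f"{tag}_density_{comp}"] = (
                count / area if area > 0 else float("nan")
            )
    n_stromal = int(in_stroma.sum())
    n_stromal_lym = int(
        (in_stroma & (df["phenotype"] == Phenotype.LYMPHOCYTE.value)).sum()
    )
    out["stromal_lymphocyte_percentage"] = (
        100.0 * n_stromal_lym / n_stromal if n_stromal > 0 else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

_DIRECTIONS = (
    # (prefix, reference, target): "lym_tumor" = lymphocytes as reference
    # measuring distances/counts to tumor cells (lymphocyte-centric).
    ("lym_tumor", Phenotype.LYMPHOCYTE, Phenotype.TUMOR),
    ("tumor_lym", Phenotype.TUMOR, Phenotype.LYMPHOCYTE),
)


def feature_names(
    proximity: ProximityConfig = ProximityConfig(),
    aggregates: AggregateConfig = AggregateConfig(),
) -> list[str]:
    """Stable ordered list of feature-column names for given configs."""
    names = []
    for prefix, _, _ in _DIRECTIONS:
        for r in proximity.radii_um:
            ri = _fmt_radius(r)
            names += [
                f"{prefix}.avg_count_{ri}",
                f"{prefix}.avg_density_{ri}",
                f"{prefix}.avg_min_distance_{ri}",
            ]
    for n in aggregates.size_thresholds:
        names += [
            f"aggregate_{n}_count",
            f"aggregate_{n}_density",
            f"aggregate_{n}_mean_cells",
        ]
    for tag in ("lym", "tumor"):
        for comp in ("tumor_region", "stroma", "total"):
            names += [f"{tag}_count_{comp}", f"{tag}_density_{comp}"]
    names.append("stromal_lymphocyte_percentage")
    return names


def _fmt_radius(r: float) -> str:
    return str(int(r)) if float(r).is_integer() else str(r)


def extract_features(
    cellmap: CellMap,
    proximity: ProximityConfig = ProximityConfig(),
    aggregates: AggregateConfig = AggregateConfig(),
) -> pd.Series:
    """All named spatial features for one sample, as a named Series.

    Cells are canonically ordered by cell_id before any computation, so
    the result is bit-identical under permutation of input rows.
    """
    proximity.validate()
    aggregates.validate()
    cellmap = CellMap(
        sample_id=cellmap.sample_id,
        cells=cellmap.cells.sort_values("cell_id", kind="stable").reset_index(drop=True),
        geometry=cellmap.geometry,
        microns_per_pixel=cellmap.microns_per_pixel,
    )
    out: dict[str, float] = {}
    for prefix, ref, tgt in _DIRECTIONS:
        n_ref = len(cellmap.coords(ref))
        if n_ref == 0:
            for r in proximity.radii_um:
                ri = _fmt_radius(r)
                out[f"{prefix}.avg_count_{ri}"] = float("nan")
                out[f"{prefix}.avg_density_{ri}"] = float("nan")
                out[f"{prefix}.avg_min_distance_{ri}"] = float("nan")
            continue
        nearest = nearest_target_distances(cellmap, ref, tgt)
        ref_xy = cellmap.coords(ref)
        tgt_xy = cellmap.coords(tgt)
        tree = cKDTree(tgt_xy) if len(tgt_xy) else None
        for r in proximity.radii_um:
            ri = _fmt_radius(r)
            if tree is not None:
                counts = tree.query_ball_point(ref_xy, r, return_length=True)
                avg_count = float(np.mean(counts))
            else:
                avg_count = 0.0
            disk_mm2 = math.pi * r * r / UM2_PER_MM2
            out[f"{prefix}.avg_count_{ri}"] = avg_count
            out[f"{prefix}.avg_density_{ri}"] = avg_count / disk_mm2
            q = nearest[np.isfinite(nearest) & (nearest <= r)]
            out[f"{prefix}.avg_min_distance_{ri}"] = (
                float(q.mean()) if q.size else float("nan")
            )
    clusters = detect_aggregates(cellmap, Phenotype.LYMPHOCYTE, aggregates)
    if clusters:
        out.update(
            aggregate_features(
                clusters, aggregates.size_thresholds,
                cellmap.geometry.tissue_area_mm2,
            )
        )
    else:
        for n in aggregates.size_thresholds:
            out[f"aggregate_{n}_count"] = float("nan")
            out[f"aggregate_{n}_density"] = float("nan")
            out[f"aggregate_{n}_mean_cells"] = float("nan")
    out.update(compartment_quantification(cellmap))
    return pd.Series(out, name=cellmap.sample_id).reindex(
        feature_names(proximity, aggregates)
    )


def extract_cohort_features(
    cellmaps: Iterable[CellMap],
    proximity: ProximityConfig = ProximityConfig(),
    aggregates: AggregateConfig = AggregateConfig(),
) -> pd.DataFrame:
    """Feature table (samples × features) for a collection of cell maps."""
    rows = [extract_features(cm, proximity, aggregates) for cm in cellmaps]
    df = pd.DataFrame(rows)
    df.index.name = "sample_id"
    return df
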