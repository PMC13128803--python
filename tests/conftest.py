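import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from tilspatial.cellmap import (
    CellMap,
    CompartmentGeometry,
    Phenotype,
    assign_compartments,
)

PHENOTYPES = [p.value for p in Phenotype]


@pytest.fixture
def rect_geometry():
    """1000×1000 μm tissue with two tumor disks."""
    tissue = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
    nests = (
        Point(300, 300).buffer(150, quad_segs=32),
        Point(700, 650).buffer(120, quad_segs=32),
    )
    return CompartmentGeometry(tissue_polygon=tissue, tumor_polygons=nests)


def make_random_cellmap(rng, n_cells=200, geometry=None, sample_id="random"):
    """Uniform random cells in the tissue with random phenotypes."""
    if geometry is None:
        tissue = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        nests = (Point(300, 300).buffer(150, quad_segs=32),)
        geometry = CompartmentGeometry(tissue_polygon=tissue, tumor_polygons=nests)
    x0, y0, x1, y1 = geometry.tissue_polygon.bounds
    x = rng.uniform(x0, x1, n_cells)
    y = rng.uniform(y0, y1, n_cells)
    phenotype = rng.choice(PHENOTYPES, size=n_cells, p=[0.4, 0.4, 0.2])
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x": x,
            "y": y,
            "phenotype": phenotype,
            "compartment": assign_compartments(x, y, geometry),
        }
    )
    return CellMap(sample_id=sample_id, cells=cells, geometry=geometry).validate()


@pytest.fixture
def random_cellmap(rect_geometry):
    return make_random_cellmap(np.random.default_rng(42), 300, rect_geometry)


def build_cellmap(points, phenotypes, geometry=None, sample_id="hand"):
    """Cell map from explicit coordinates/phenotypes (compartment from geometry)."""
    pts = np.asarray(points, dtype=float)
    if geometry is None:
        pad = 500.0
        x0, y0 = pts.min(axis=0) - pad
        x1, y1 = pts.max(axis=0) + pad
        geometry = CompartmentGeometry(
            tissue_polygon=Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "phenotype": list(phenotypes),
            "compartment": assign_compartments(pts[:, 0], pts[:, 1], geometry),
        }
    )
    return CellMap(sample_id=sample_id, cells=cells, geometry=geometry).validate()


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive)
# ---------------------------------------------------------------------------

def brute_nearest(ref_xy, tgt_xy):
    """O(n²) nearest-target distances."""
    out = np.full(len(ref_xy), np.nan)
    for i, p in enumerate(ref_xy):
        best = np.inf
        for q in tgt_xy:
            dx, dy = p[0] - q[0], p[1] - q[1]
            d = math.sqrt(dx * dx + dy * dy)
            if d < best:
                best = d
        if np.isfinite(best):
            out[i] = best
    return out


def brute_counts(ref_xy, tgt_xy, r):
    """O(n²) count of targets at distance <= r from each reference."""
    out = np.zeros(len(ref_xy), dtype=int)
    for i, p in enumerate(ref_xy):
        for q in tgt_xy:
            dx, dy = p[0] - q[0], p[1] - q[1]
            if math.sqrt(dx * dx + dy * dy) <= r:
                out[i] += 1
    return out


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_clusters(xy, link_distance):
    """Single-linkage components by exhaustive pair scan + union-find."""
    n = len(xy)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) < link_distance:
                uf.union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(uf.find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def enumerate_cliques(xy, link_distance):
    """All maximal all-pairs-subthreshold subsets, by subset enumeration (n<=12)."""
    n = len(xy)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(*(xy[i] - xy[j])) < link_distance:
                adj[i, j] = True
    valid = []
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if all(adj[a][b] for k, a in enumerate(members) for b in members[k + 1:]):
            valid.append(frozenset(members))
    maximal = {
        s for s in valid if not any(s < t for t in valid)
    }
    return maximal
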