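"""Spatial feature families: oracles, hand geometry, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import Polygon

from tilspatial.cellmap import CellMap, CompartmentGeometry, Phenotype
from tilspatial.features import (
    AggregateConfig,
    EmptyInputError,
    LinkageMode,
    ProximityConfig,
    aggregate_features,
    average_min_distance,
    compartment_quantification,
    counts_within_radius,
    detect_aggregates,
    extract_features,
    feature_names,
    nearest_target_distances,
)

from conftest import (
    brute_counts,
    brute_nearest,
    build_cellmap,
    enumerate_cliques,
    make_random_cellmap,
    union_find_clusters,
)

LYM = Phenotype.LYMPHOCYTE.value
TUM = Phenotype.TUMOR.value
RADII = (10.0, 20.0, 30.0, 50.0, 100.0, 200.0)


class TestNearestTargetDistances:
    def test_forced_minimum(self):
        cm = build_cellmap([(0, 0), (5, 0), (40, 0)], [LYM, TUM, TUM])
        d = nearest_target_distances(cm, LYM, TUM)
        assert d.tolist() == [5.0]

    def test_no_targets_gives_missing(self):
        cm = build_cellmap([(0, 0), (5, 0)], [LYM, LYM])
        d = nearest_target_distances(cm, LYM, TUM)
        assert np.isnan(d).all()

    def test_no_reference_cells_is_error(self):
        cm = build_cellmap([(0, 0)], [TUM])
        with pytest.raises(EmptyInputError):
            nearest_target_distances(cm, LYM, TUM)

    def test_same_phenotype_rejected(self):
        cm = build_cellmap([(0, 0)], [TUM])
        with pytest.raises(ValueError, match="differ"):
            nearest_target_distances(cm, TUM, TUM)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            cm = make_random_cellmap(rng, 200)
            got = nearest_target_distances(cm, LYM, TUM)
            exp = brute_nearest(cm.coords(LYM), cm.coords(TUM))
            np.testing.assert_array_equal(got, exp)


class TestCountsWithinRadius:
    def test_hand_geometry(self):
        cm = build_cellmap([(0, 0), (5, 0), (25, 0)], [LYM, TUM, TUM])
        assert counts_within_radius(cm, LYM, TUM, 10).tolist() == [1]
        assert counts_within_radius(cm, LYM, TUM, 30).tolist() == [2]

    def test_radius_below_all_pairs_gives_zeros(self):
        cm = build_cellmap([(0, 0), (100, 0), (0, 100)], [LYM, TUM, TUM])
        assert counts_within_radius(cm, LYM, TUM, 1).tolist() == [0]

    def test_matches_brute_force_all_radii(self):
        rng = np.random.default_rng(32)
        for _ in range(3):
            cm = make_random_cellmap(rng, 500)
            for r in RADII:
                got = counts_within_radius(cm, LYM, TUM, r)
                exp = brute_counts(cm.coords(LYM), cm.coords(TUM), r)
                np.testing.assert_array_equal(got, exp)


class TestAverageMinDistance:
    def test_censoring_by_radius(self):
        # nearest distances per lymphocyte: 5, 15, 50
        cm = build_cellmap(
            [(0, 0), (5, 0), (100, 0), (115, 0), (300, 0), (350, 0)],
            [LYM, TUM, LYM, TUM, LYM, TUM],
        )
        assert average_min_distance(cm, LYM, TUM, 10) == pytest.approx(5.0)
        assert average_min_distance(cm, LYM, TUM, 20) == pytest.approx(10.0)

    def test_missing_when_nothing_qualifies(self):
        cm = build_cellmap([(0, 0), (500, 0)], [LYM, TUM])
        assert math.isnan(average_min_distance(cm, LYM, TUM, 10))

    def test_oracle_composition(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            cm = make_random_cellmap(rng, 300)
            d = brute_nearest(cm.coords(LYM), cm.coords(TUM))
            for r in RADII:
                q = d[np.isfinite(d) & (d <= r)]
                exp = q.mean() if q.size else float("nan")
                got = average_min_distance(cm, LYM, TUM, r)
                if math.isnan(exp):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(exp, rel=1e-12)


class TestAggregates:
    def test_single_linkage_chains(self):
        cm = build_cellmap([(0, 0), (15, 0), (30, 0)], [LYM] * 3)
        clusters = detect_aggregates(cm, LYM, AggregateConfig())
        assert {len(c) for c in clusters} == {3}

    def test_no_edges_gives_singletons(self):
        cm = build_cellmap([(0, 0), (50, 0)], [LYM, LYM])
        clusters = detect_aggregates(cm, LYM, AggregateConfig())
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_strict_inequality_at_threshold(self):
        cm = build_cellmap([(0, 0), (20, 0)], [LYM, LYM])  # exactly 20 μm apart
        clusters = detect_aggregates(cm, LYM, AggregateConfig())
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_clique_mode_on_chain(self):
        cm = build_cellmap([(0, 0), (15, 0), (30, 0)], [LYM] * 3)
        config = AggregateConfig(linkage_mode=LinkageMode.CLIQUE)
        clusters = detect_aggregates(cm, LYM, config)
        assert sorted(len(c) for c in clusters) == [2, 2]

    def test_single_linkage_matches_union_find_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(5):
            cm = make_random_cellmap(rng, 150)
            got = detect_aggregates(cm, LYM, AggregateConfig())
            xy = cm.coords(LYM)
            ids = cm.subset_ids(LYM)
            exp = union_find_clusters(xy, 20.0)
            exp_ids = {frozenset(ids[i] for i in c) for c in exp}
            assert set(got) == exp_ids

    def test_single_linkage_partitions_cells(self):
        cm = make_random_cellmap(np.random.default_rng(35), 300)
        clusters = detect_aggregates(cm, LYM, AggregateConfig())
        all_ids = [i for c in clusters for i in c]
        assert sorted(all_ids) == sorted(cm.subset_ids(LYM))

    def test_clique_mode_matches_enumeration(self):
        rng = np.random.default_rng(36)
        config = AggregateConfig(linkage_mode=LinkageMode.CLIQUE)
        for _ in range(5):
            n = int(rng.integers(4, 13))
            xy = rng.uniform(0, 60, size=(n, 2))
            cm = build_cellmap(xy, [LYM] * n)
            got = {
                frozenset(c) for c in detect_aggregates(cm, LYM, config)
            }
            exp = {
                frozenset(int(i) for i in c)
                for c in enumerate_cliques(cm.coords(LYM), 20.0)
            }
            assert got == exp  # cell_id == row index in build_cellmap


class TestAggregateFeatures:
    def test_counting_and_mean(self):
        clusters = [frozenset(range(2)), frozenset(range(10, 13)),
                    frozenset(range(20, 25))]
        out = aggregate_features(clusters, [2, 3, 4, 5], tissue_area_mm2=4.0)
        assert out["aggregate_2_count"] == 3
        assert out["aggregate_4_count"] == 1
        assert out["aggregate_4_mean_cells"] == 5.0

    def test_density_is_count_per_area(self):
        clusters = [frozenset(range(3)), frozenset(range(10, 14))]
        out = aggregate_features(clusters, [2], tissue_area_mm2=4.0)
        assert out["aggregate_2_density"] == pytest.approx(0.5)

    def test_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            sizes = rng.integers(1, 12, size=rng.integers(1, 40))
            clusters = [frozenset(range(int(s))) for s in sizes]
            out = aggregate_features(clusters, [2, 3, 4, 5], 1.0)
            counts = [out[f"aggregate_{n}_count"] for n in (2, 3, 4, 5)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCompartmentQuantification:
    def test_stromal_lymphocyte_percentage(self, rect_geometry):
        # 10 stromal lymphocytes among 40 stromal cells
        rng = np.random.default_rng(38)
        pts, phenos = [], []
        for i in range(40):
            pts.append((900 + rng.uniform(-40, 40), 60 + rng.uniform(-40, 40)))
            phenos.append(LYM if i < 10 else Phenotype.OTHER.value)
        cm = build_cellmap(pts, phenos, geometry=rect_geometry)
        out = compartment_quantification(cm)
        assert out["stromal_lymphocyte_percentage"] == pytest.approx(25.0)

    def test_density_uses_compartment_area(self):
        tissue = Polygon([(0, 0), (2000, 0), (2000, 1000), (0, 1000)])
        geom = CompartmentGeometry(tissue_polygon=tissue)  # all stroma, 2 mm²
        rng = np.random.default_rng(39)
        pts = rng.uniform(1, 999, size=(300, 2)) * [2, 1]
        cm = build_cellmap(pts, [LYM] * 300, geometry=geom)
        out = compartment_quantification(cm)
        assert out["lym_density_stroma"] == pytest.approx(150.0)

    def test_counts_conserve_across_compartments(self):
        rng = np.random.default_rng(40)
        for _ in range(5):
            cm = make_random_cellmap(rng, 250)
            out = compartment_quantification(cm)
            for tag in ("lym", "tumor"):
                assert out[f"{tag}_count_total"] == (
                    out[f"{tag}_count_tumor_region"] + out[f"{tag}_count_stroma"]
                )


class TestExtractFeatures:
    def test_feature_count_from_configuration(self):
        names = feature_names()
        assert len(names) == 2 * 6 * 3 + 4 * 3 + 13

    def test_no_lymphocytes_degenerate(self, rect_geometry):
        cm = build_cellmap(
            [(300, 300), (310, 300)], [TUM, TUM], geometry=rect_geometry
        )
        fv = extract_features(cm)
        assert np.isnan(fv["lym_tumor.avg_min_distance_10"])
        assert np.isnan(fv["aggregate_2_count"])
        assert fv["lym_count_total"] == 0
        assert fv["tumor_count_total"] == 2

    def test_row_permutation_bit_identical(self, random_cellmap):
        fv1 = extract_features(random_cellmap)
        shuffled = CellMap(
            sample_id=random_cellmap.sample_id,
            cells=random_cellmap.cells.sample(
                frac=1.0, random_state=5
            ).reset_index(drop=True),
            geometry=random_cellmap.geometry,
        )
        fv2 = extract_features(shuffled)
        pd.testing.assert_series_equal(fv1, fv2, check_exact=True, check_names=False)

    def test_translation_rotation_invariance(self, random_cellmap):
        fv1 = extract_features(random_cellmap)
        angle, dx, dy = 37.0, 1234.5, -987.6
        origin = (0.0, 0.0)

        def transform_poly(p):
            return affinity.translate(
                affinity.rotate(p, angle, origin=origin), dx, dy
            )

        theta = math.radians(angle)
        c, s = math.cos(theta), math.sin(theta)
        cells = random_cellmap.cells.copy()
        x, y = cells["x"].to_numpy(), cells["y"].to_numpy()
        cells["x"] = c * x - s * y + dx
        cells["y"] = s * x + c * y + dy
        geom = CompartmentGeometry(
            tissue_polygon=transform_poly(random_cellmap.geometry.tissue_polygon),
            tumor_polygons=tuple(
                transform_poly(p) for p in random_cellmap.geometry.tumor_polygons
            ),
        )
        moved = CellMap(sample_id="moved", cells=cells, geometry=geom)
        fv2 = extract_features(moved)
        for name in fv1.index:
            a, b = fv1[name], fv2[name]
            if np.isnan(a):
                assert np.isnan(b), name
            else:
                assert b == pytest.approx(a, rel=1e-9, abs=1e-9), name

    def test_min_distance_monotone_and_bounded(self, random_cellmap):
        fv = extract_features(random_cellmap)
        prev = -np.inf
        for r in RADII:
            v = fv[f"lym_tumor.avg_min_distance_{int(r)}"]
            if np.isnan(v):
                continue
            assert v <= r
            assert v >= prev
            prev = v

    def test_avg_count_monotone_in_radius(self, random_cellmap):
        fv = extract_features(random_cellmap)
        counts = [fv[f"lym_tumor.avg_count_{int(r)}"] for r in RADII]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
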