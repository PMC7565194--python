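"""Density maps, neighbor counting, region delineation and composition."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import label as cc_label

from cycifpipe.errors import InputError, ParameterError
from cycifpipe.spatial import (
    define_regions,
    density_map,
    neighbor_count,
    region_composition,
    RegionMask,
)


def brute_force_counts(reference, centroids, distance_px):
    """Independent oracle: per-object Euclidean distance from each
    rasterized centroid to the object's pixel set."""
    pts = np.rint(np.asarray(centroids, float)).astype(int)
    out = {}
    for obj in [int(v) for v in np.unique(reference) if v != 0]:
        coords = np.argwhere(reference == obj)
        n = 0
        for p in pts:
            d = np.sqrt(((coords - p) ** 2).sum(axis=1)).min()
            if d <= distance_px:
                n += 1
        out[obj] = n
    return out


class TestDensityMap:
    def test_no_points_gives_zero_map(self):
        dm = density_map(np.zeros((0, 2)), (100, 100), bandwidth_px=10)
        assert dm.grid.sum() == 0.0
        assert dm.total_count == 0

    def test_single_point_mass_conserved_even_at_border(self):
        for pt in [(50.0, 50.0), (0.0, 0.0), (99.0, 3.0), (1.2, 98.7)]:
            dm = density_map([pt], (100, 100), bandwidth_px=15, downsample=4)
            assert dm.grid.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_clusters_carry_their_own_mass(self, rng):
        c1 = rng.normal((100, 100), 5, (50, 2))
        c2 = rng.normal((100, 500), 5, (50, 2))
        pts = np.vstack([c1, c2])
        dm = density_map(pts, (200, 600), bandwidth_px=20, downsample=2)
        rr, cc = np.mgrid[0 : dm.grid.shape[0], 0 : dm.grid.shape[1]]
        full_r = (rr + 0.5) * 2 - 0.5
        full_c = (cc + 0.5) * 2 - 0.5
        near1 = np.hypot(full_r - 100, full_c - 100) <= 100
        near2 = np.hypot(full_r - 100, full_c - 500) <= 100
        assert dm.grid[near1].sum() == pytest.approx(50, abs=1)
        assert dm.grid[near2].sum() == pytest.approx(50, abs=1)

    def test_total_mass_equals_point_count(self, rng):
        pts = rng.uniform(0, 255, (137, 2))
        dm = density_map(pts, (256, 256), bandwidth_px=12, downsample=4)
        assert dm.grid.sum() == pytest.approx(137, abs=1e-6)

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(InputError):
            density_map([(300.0, 10.0)], (256, 256), bandwidth_px=10)


class TestNeighborCount:
    def square_reference(self):
        ref = np.zeros((100, 100), np.int32)
        ref[40:60, 40:60] = 1
        return ref

    def test_distance_zero_counts_only_centroids_on_object(self):
        ref = self.square_reference()
        targets = np.array([[50.0, 50.0], [50.0, 65.0]])
        counts = neighbor_count(ref, targets, 0)
        assert counts.per_object == {1: 1}
        assert counts.total_unique == 1

    def test_targets_at_known_distances_from_boundary(self):
        ref = self.square_reference()
        # boundary at col 59; distances 5 and 15 from the object
        targets = np.array([[50.0, 64.0], [50.0, 74.0]])
        counts = neighbor_count(ref, targets, 10)
        assert counts.per_object == {1: 1}

    def test_shared_target_counts_once_per_object_and_once_in_total(self):
        ref = np.zeros((60, 60), np.int32)
        ref[10:20, 10:20] = 1
        ref[10:20, 30:40] = 2
        target = np.array([[15.0, 25.0]])  # within 6 px of both
        counts = neighbor_count(ref, target, 6)
        assert counts.per_object == {1: 1, 2: 1}
        assert counts.total_unique == 1

    def test_negative_distance_rejected(self):
        with pytest.raises(ParameterError):
            neighbor_count(self.square_reference(), np.zeros((0, 2)), -1)

    @pytest.mark.parametrize("radius", [0, 6, 10])
    def test_matches_brute_force_oracle_exactly(self, radius, rng):
        for _ in range(5):
            ref = np.zeros((120, 120), np.int32)
            for obj in range(1, rng.integers(3, 10)):
                r, c = rng.integers(10, 110, 2)
                rr, cc = draw_disk((r, c), rng.integers(2, 6), shape=ref.shape)
                ref[rr, cc] = obj
            targets = rng.uniform(0, 119, (50, 2))
            counts = neighbor_count(ref, targets, radius)
            assert counts.per_object == brute_force_counts(ref, targets, radius)

    def test_per_area_normalization(self):
        ref = self.square_reference()
        targets = np.array([[50.0, 50.0]])
        tissue = np.ones((100, 100), bool)
        counts = neighbor_count(ref, targets, 0, tissue_mask=tissue)
        assert counts.per_area == pytest.approx(1 / 10000)


def ring_mask(shape, center, r_in, r_out):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return (d >= r_in) & (d < r_out)


def pcna_labels(shape, centers):
    mask = np.zeros(shape, bool)
    for c in centers:
        rr, cc = draw_disk(c, 3, shape=shape)
        mask[rr, cc] = True
    return cc_label(mask, connectivity=1)


class TestDefineRegions:
    def test_empty_collagen_gives_single_extratumoral_region(self):
        regions = define_regions(
            np.zeros((64, 64), bool), np.zeros((64, 64), np.int32)
        )
        assert regions.n_tumors == 0
        assert (regions.labels == 0).all()

    def test_ring_with_enough_pcna_nuclei_becomes_tumor(self, rng):
        shape = (200, 200)
        collagen = ring_mask(shape, (100, 100), 60, 66)
        centers = [
            (100 + dr, 100 + dc)
            for dr, dc in rng.integers(-35, 35, (20, 2))
        ]
        regions = define_regions(
            collagen, pcna_labels(shape, centers), min_pcna_nuclei=10
        )
        assert regions.n_tumors == 1
        truth = np.hypot(*np.mgrid[0:200, 0:200] - np.array([[[100]], [[100]]])) < 60
        pred = regions.labels == regions.tumor_ids[0]
        assert (pred & truth).sum() / (pred | truth).sum() >= 0.9

    def test_ring_without_pcna_is_not_a_tumor(self):
        shape = (200, 200)
        collagen = ring_mask(shape, (100, 100), 60, 66)
        regions = define_regions(collagen, np.zeros(shape, np.int32))
        assert regions.n_tumors == 0

    def test_monotone_in_min_pcna_nuclei(self, rng):
        shape = (200, 200)
        collagen = ring_mask(shape, (100, 100), 60, 66)
        centers = [
            (100 + dr, 100 + dc)
            for dr, dc in rng.integers(-35, 35, (12, 2))
        ]
        nuclei = pcna_labels(shape, centers)
        previous = None
        for threshold in (1, 5, 10, 15, 50):
            n = define_regions(
                collagen, nuclei, min_pcna_nuclei=threshold
            ).n_tumors
            if previous is not None:
                assert n <= previous
            previous = n

    def test_gap_in_capsule_sealed_by_closing(self):
        shape = (200, 200)
        collagen = ring_mask(shape, (100, 100), 60, 66)
        collagen[98:103, :] &= False  # cut a 5 px channel through the ring
        centers = [(100 + dr, 100 + dc) for dr in (-20, 0, 20) for dc in (-20, 0, 20)]
        regions = define_regions(
            collagen, pcna_labels(shape, centers), closing_px=10, min_pcna_nuclei=5
        )
        assert regions.n_tumors == 1


class TestRegionComposition:
    def make_table(self, centers, phenotypes):
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, len(centers) + 1),
                "centroid_row": [c[0] for c in centers],
                "centroid_col": [c[1] for c in centers],
                "area_px": 50,
                "phenotype": phenotypes,
            }
        )

    def test_single_region_equals_whole_table_composition(self):
        labels = np.zeros((50, 50), np.int32)
        regions = RegionMask(labels=labels, classes={0: "extratumoral"})
        table = self.make_table([(10, 10), (20, 20), (30, 30)], ["KC", "KC", "MoMF"])
        comp = region_composition(regions, table)
        kc = comp[(comp.phenotype == "KC")].iloc[0]
        assert kc["n_cells"] == 2
        assert kc["fraction_of_region"] == pytest.approx(2 / 3)

    def test_cells_conserved_across_regions(self, rng):
        labels = np.zeros((100, 100), np.int32)
        labels[20:50, 20:50] = 1
        regions = RegionMask(labels=labels, classes={0: "extratumoral", 1: "tumor"})
        centers = [tuple(c) for c in rng.uniform(0, 99, (60, 2))]
        phenos = rng.choice(["KC", "MoMF", "other"], 60)
        comp = region_composition(regions, self.make_table(centers, phenos))
        assert comp["n_cells"].sum() == 60
        per_pheno = comp.groupby("phenotype")["n_cells"].sum()
        for p in ("KC", "MoMF", "other"):
            assert per_pheno.get(p, 0) == (phenos == p).sum()

    def test_macrophage_compartment_fractions(self):
        labels = np.zeros((50, 50), np.int32)
        regions = RegionMask(labels=labels, classes={0: "extratumoral"})
        table = self.make_table(
            [(5, 5), (10, 10), (15, 15), (20, 20)],
            ["KC", "KC", "MoMF", "other"],
        )
        comp = region_composition(regions, table).set_index("phenotype")
        assert comp.loc["KC", "fraction_of_macrophages"] == pytest.approx(2 / 3)
        assert comp.loc["MoMF", "fraction_of_macrophages"] == pytest.approx(1 / 3)
        assert np.isnan(comp.loc["other", "fraction_of_macrophages"])
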