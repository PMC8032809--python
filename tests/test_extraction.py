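"""Mask-to-particle extraction, checked against independent oracles."""
import itertools

import numpy as np
import pytest

from goldpick.extraction import (
    ExtractionParams,
    binarize,
    cluster_sizes,
    component_stats,
    connected_components,
    extract_particles,
)
from goldpick.synthetic import SceneSpec, render_scene, render_target_mask
from goldpick.types import GroundTruthParticle


# --- independent oracles ------------------------------------------------

def flood_fill_labels(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """Brute-force BFS labeling, independent of scipy."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return comps


def optimal_partition_cost(values: np.ndarray, k: int) -> float:
    """Exhaustive best contiguous k-partition of sorted values (sq. deviation)."""
    v = np.sort(values)
    n = len(v)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        cost = 0.0
        for a, b in zip(edges, edges[1:]):
            seg = v[a:b]
            cost += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, cost)
    return best


def _labels_cost(values: np.ndarray, labels: np.ndarray) -> float:
    return sum(
        float(((seg := values[labels == g]) - seg.mean()).dot(seg - seg.mean()))
        for g in np.unique(labels)
    )


# --- tests --------------------------------------------------------------

class TestBinarize:
    def test_all_background(self):
        assert not binarize(np.zeros((8, 8)), 0.5).any()

    def test_threshold_at_minimum_keeps_everything(self):
        data = np.random.default_rng(0).random((8, 8))
        assert binarize(data, data.min()).all()

    def test_ramp_count_closed_form(self):
        ramp = np.tile(np.arange(100) / 99.0, (10, 1))
        # columns with value >= 0.5: ceil(99*0.5)=50 ... 99 -> 50 columns
        assert binarize(ramp, 0.5).sum() == 10 * 50


class TestConnectedComponents:
    def test_diagonal_pixels_connectivity(self):
        binary = np.zeros((4, 4), bool)
        binary[1, 1] = binary[2, 2] = True
        assert connected_components(binary, 8).max() == 1
        assert connected_components(binary, 4).max() == 2

    def test_empty_mask(self):
        assert connected_components(np.zeros((5, 5), bool), 8).max() == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            binary = rng.random((32, 32)) < 0.35
            labels = connected_components(binary, connectivity)
            got = {
                frozenset(zip(*np.nonzero(labels == lab)))
                for lab in range(1, labels.max() + 1)
            }
            expected = set(flood_fill_labels(binary, connectivity))
            assert got == expected

    def test_labels_in_raster_order(self):
        binary = np.zeros((6, 6), bool)
        binary[4, 0] = True
        binary[0, 4] = True
        labels = connected_components(binary, 8)
        assert labels[0, 4] == 1 and labels[4, 0] == 2


class TestComponentStats:
    def test_single_pixel(self):
        comp = np.zeros((6, 8), bool)
        comp[3, 5] = True
        assert component_stats(comp) == (5.0, 3.0, 1)

    def test_square_symmetry(self):
        comp = np.zeros((12, 12), bool)
        comp[0:11, 0:11] = True
        assert component_stats(comp) == (5.0, 5.0, 121)

    def test_matches_hand_summed_mean(self, rng):
        rows = rng.integers(0, 20, size=10)
        cols = rng.integers(0, 20, size=10)
        x, y, area = component_stats((rows, cols))
        assert area == 10
        assert x == pytest.approx(sum(cols) / 10)
        assert y == pytest.approx(sum(rows) / 10)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            component_stats(np.zeros((3, 3), bool))


class TestClusterSizes:
    def test_two_obvious_groups(self):
        labels, means = cluster_sizes([20, 22, 24, 90, 95, 100], 2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert means[0] == pytest.approx(22.0)
        assert means[1] == pytest.approx(95.0)

    def test_single_group(self):
        labels, means = cluster_sizes([50, 50, 50], 1)
        assert labels.tolist() == [0, 0, 0]
        assert means[0] == 50.0

    def test_6nm_12nm_footprints_separate_perfectly(self):
        # equivalent-disk areas at 1.11 nm/px: ~23 px^2 and ~92 px^2
        small = [21, 23, 25]
        large = [88, 92, 96]
        labels, _ = cluster_sizes(small + large, 2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_matches_exhaustive_partition_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(1, min(4, n) + 1))
            areas = rng.integers(1, 300, size=n).astype(float)
            labels, _ = cluster_sizes(areas, k)
            got = _labels_cost(np.sqrt(areas), labels)
            best = optimal_partition_cost(np.sqrt(areas), k)
            assert got == pytest.approx(best, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        areas = rng.integers(1, 200, size=10)
        labels, _ = cluster_sizes(areas, 3)
        perm = rng.permutation(10)
        labels_p, _ = cluster_sizes(areas[perm], 3)
        assert labels_p.tolist() == labels[perm].tolist()

    def test_too_few_areas_rejected(self):
        with pytest.raises(ValueError):
            cluster_sizes([5], 2)


class TestExtractParticles:
    def test_single_12nm_target_mask(self):
        mask = render_target_mask([GroundTruthParticle(30.0, 40.0, 12.0)], 64, 64, 1.11)
        recs = extract_particles(mask, ExtractionParams(n_groups=1))
        assert len(recs) == 1
        r = recs[0]
        assert (r.x_px, r.y_px) == (30.0, 40.0)
        assert r.area_px == 121
        # equivalent-circle diameter of an 11x11 square: 2*sqrt(121/pi)*1.11
        assert r.diameter_nm_est == pytest.approx(13.77, abs=0.01)

    def test_min_area_filters_specks(self):
        mask = np.zeros((16, 16), dtype=np.float32)
        mask[3, 3] = 1.0
        assert extract_particles(mask, ExtractionParams(min_area_px=4)) == []

    def test_two_size_scene_group_counts_match_truth(self):
        spec = SceneSpec(height_px=256, width_px=256, counts_per_diameter=(5, 3))
        pair = render_scene(spec, seed=21)
        recs = extract_particles(pair.target_mask, ExtractionParams())
        assert len(recs) == 8
        assert sum(1 for r in recs if r.group == 0) == 5
        assert sum(1 for r in recs if r.group == 1) == 3

    def test_component_areas_partition_foreground(self, rng):
        mask = (rng.random((64, 64)) < 0.3).astype(np.float32)
        params = ExtractionParams(min_area_px=0, n_groups=1)
        recs = extract_particles(mask, params)
        assert sum(r.area_px for r in recs) == int((mask >= 0.5).sum())

    def test_records_sorted_by_position(self):
        truth = [
            GroundTruthParticle(40.0, 10.0, 12.0),
            GroundTruthParticle(10.0, 40.0, 12.0),
            GroundTruthParticle(45.0, 40.0, 6.0),
        ]
        mask = render_target_mask(truth, 64, 64, 1.11)
        recs = extract_particles(mask, ExtractionParams())
        assert [(r.y_px, r.x_px) for r in recs] == sorted(
            (r.y_px, r.x_px) for r in recs
        )

    def test_empty_mask_gives_empty_list(self):
        assert extract_particles(np.zeros((32, 32), np.float32), ExtractionParams()) == []
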