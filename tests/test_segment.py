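import numpy as np
import pytest
from scipy import ndimage, stats

from strobetrack import (
    CameraModel,
    Movie,
    filter_colonies,
    filter_dim_cells,
    group_colonies,
    segment_cells,
    to_cell_coordinates,
)


def binary_ellipse(shape, cx, cy, a, b, angle=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    X = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    Y = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    return (X / a) ** 2 + (Y / b) ** 2 <= 1.0


def flat_movie(value, n_frames=10, shape=(96, 96)):
    cam = CameraModel(gain=1.0, offset=0.0, read_noise=0.0)
    data = np.full((n_frames,) + shape, value, dtype=np.uint16)
    return Movie(data, 65.7, 0.005, 0.003, cam)


class TestSegmentCells:
    def test_single_ellipse_recovered(self):
        img = binary_ellipse((96, 96), 48.0, 40.0, 25, 8, angle=0.4).astype(float)
        regs = segment_cells(img)
        assert len(regs) == 1
        r = regs[0]
        assert abs(r.centroid[0] - 48.0) < 0.5 and abs(r.centroid[1] - 40.0) < 0.5
        assert abs(r.axes[0] / 25 - 1) < 0.05
        assert abs(r.axes[1] / 8 - 1) < 0.05

    def test_blank_image_yields_no_regions(self):
        assert segment_cells(np.zeros((64, 64))) == []

    def test_two_disjoint_ellipses(self):
        img = binary_ellipse((96, 96), 25, 25, 15, 6) | binary_ellipse((96, 96), 70, 70, 15, 6)
        assert len(segment_cells(img.astype(float))) == 2

    def test_label_mask_bypasses_thresholding(self, ideal_mask):
        regs = segment_cells(None, label_mask=ideal_mask)
        assert len(regs) == 1 and regs[0].label == 1


class TestColonies:
    def make_regions(self, centers, shape=(128, 128)):
        mask = np.zeros(shape, dtype=np.uint16)
        for i, (cx, cy) in enumerate(centers):
            mask[binary_ellipse(shape, cx, cy, 12, 5)] = i + 1
        return segment_cells(None, label_mask=mask, min_area=10)

    def test_touching_cells_share_a_colony(self):
        regs = group_colonies(self.make_regions([(40, 40), (40, 50)]), gap_px=2)
        assert regs[0].colony == regs[1].colony

    def test_distant_cells_split_colonies(self):
        regs = group_colonies(self.make_regions([(30, 30), (30, 90)]), gap_px=5)
        assert regs[0].colony != regs[1].colony

    def test_transitive_chain_forms_single_colony(self):
        # chain A-B-C where only consecutive pairs touch: one component,
        # matching a connected-components oracle on the adjacency graph
        centers = [(30, 40), (30, 52), (30, 64)]
        regs = group_colonies(self.make_regions(centers), gap_px=2)
        assert len({r.colony for r in regs}) == 1

    def test_colony_size_filter_boundary(self):
        # 9 touching cells -> whole colony removed; 8 -> retained
        for n, expect in [(9, 0), (8, 8)]:
            centers = [(30, 20 + 11 * i) for i in range(n)]
            regs = group_colonies(self.make_regions(centers), gap_px=2)
            assert len({r.colony for r in regs}) == 1
            assert len(filter_colonies(regs, max_cells=8)) == expect

    def test_empty_input_passes_through(self):
        assert filter_colonies([]) == []


class TestDimFilter:
    def make_setup(self, cell_value, bg_value=10.0):
        mask = np.zeros((96, 96), dtype=np.uint16)
        mask[binary_ellipse((96, 96), 48, 48, 20, 7)] = 1
        regs = segment_cells(None, label_mask=mask)
        img = np.full((96, 96), bg_value)
        img[mask == 1] = cell_value
        data = np.repeat(img[None], 10, axis=0).astype(np.uint16)
        movie = Movie(data, 65.7, 0.005, 0.003, CameraModel(1.0, 0.0, 0.0))
        return movie, regs

    def test_cell_at_exact_threshold_removed(self):
        movie, regs = self.make_setup(cell_value=11.0, bg_value=10.0)
        assert filter_dim_cells(movie, regs, ratio=1.1) == []

    def test_bright_cell_retained(self):
        movie, regs = self.make_setup(cell_value=20.0, bg_value=10.0)
        assert len(filter_dim_cells(movie, regs, ratio=1.1)) == 1

    def test_uniform_image_removes_everything(self):
        movie, regs = self.make_setup(cell_value=10.0, bg_value=10.0)
        assert filter_dim_cells(movie, regs, ratio=1.0) == []

    def test_short_movie_rejected(self):
        movie, regs = self.make_setup(cell_value=20.0)
        short = Movie(movie.data[:5], 65.7, 0.005, 0.003, movie.camera)
        with pytest.raises(ValueError):
            filter_dim_cells(short, regs)

    def test_filters_commute_and_are_idempotent(self):
        movie, regs = self.make_setup(cell_value=20.0)
        regs = group_colonies(regs)
        a = filter_dim_cells(movie, filter_colonies(regs), ratio=1.1)
        b = filter_colonies(filter_dim_cells(movie, regs, ratio=1.1))
        assert [r.label for r in a] == [r.label for r in b]
        assert [r.label for r in filter_colonies(a)] == [r.label for r in a]


class TestNormalizedCoordinates:
    def region(self, ideal_mask):
        return segment_cells(None, label_mask=ideal_mask)[0]

    def test_centroid_maps_to_cell_middle(self, ideal_mask):
        r = self.region(ideal_mask)
        p = to_cell_coordinates(r, r.centroid)
        assert abs(p.l - 0.5) < 0.05 and abs(p.s) < 0.05

    def test_pole_tips_map_to_ends(self, ideal_mask):
        r = self.region(ideal_mask)
        for tip in r.backbone:
            p = to_cell_coordinates(r, (tip[0], tip[1]))
            assert min(p.l, 1 - p.l) < 0.02

    def test_boundary_point_at_midcell_has_unit_offset(self, cell, ideal_mask):
        r = self.region(ideal_mask)
        px = 65.7 / 1000
        u = cell.direction[:2]
        n = np.array([-u[1], u[0]])
        pt = (np.array(cell.center) + 0.98 * cell.radius * n) / px
        p = to_cell_coordinates(r, (pt[0], pt[1]))
        assert abs(abs(p.s) - 1.0) < 0.1

    def test_point_far_outside_rejected(self, ideal_mask):
        r = self.region(ideal_mask)
        with pytest.raises(ValueError):
            to_cell_coordinates(r, (2.0, 2.0))

    def test_longitudinal_marginal_uniform_on_cylinder(self, cell, ideal_mask, rng):
        """Uniform interior points have a flat l-marginal away from the caps."""
        r = self.region(ideal_mask)
        px = 65.7 / 1000
        pts = cell.sample_volume(4000, rng)[:, :2] / px
        ls = []
        for x, y in pts:
            try:
                ls.append(to_cell_coordinates(r, (x, y)).l)
            except ValueError:
                pass
        ls = np.array(ls)
        cap = cell.radius / cell.length
        body = ls[(ls > cap + 0.05) & (ls < 1 - cap - 0.05)]
        counts, _ = np.histogram(body, bins=8, range=(cap + 0.05, 1 - cap - 0.05))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rotation_equivariance_up_to_pole_relabel(self, ideal_mask):
        r0 = self.region(ideal_mask)
        pt = (r0.centroid[0] + 10.0, r0.centroid[1] + 3.0)
        p0 = to_cell_coordinates(r0, pt)
        rot = np.rot90(ideal_mask).copy()
        r1 = segment_cells(None, label_mask=rot)[0]
        h = ideal_mask.shape[1]
        pt_rot = (pt[1], h - 1 - pt[0])  # 90 deg CCW pixel map
        p1 = to_cell_coordinates(r1, pt_rot)
        dl = min(abs(p1.l - p0.l), abs((1 - p1.l) - p0.l))
        assert dl < 0.02 and abs(abs(p1.s) - abs(p0.s)) < 0.05
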