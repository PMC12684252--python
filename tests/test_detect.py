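import numpy as np
import pandas as pd
import pytest

from strobetrack import (
    CameraModel,
    detect_candidates,
    filter_localizations,
    map_refine,
    radial_symmetry_center,
    segment_cells,
)
from strobetrack.detect import _pixel_integrated_gaussian


def spot_frame(shape, x, y, photons=500, bg=5.0, sigma=1.3):
    h, w = shape
    img = np.full((h, w), float(bg))
    half = 10
    cx, cy = int(round(x)), int(round(y))
    n = 2 * half + 1
    g = _pixel_integrated_gaussian(n, x - cx + half, y - cy + half, sigma)
    img[cy - half : cy + half + 1, cx - half : cx + half + 1] += photons * g
    return img


def spot_roi(n, x, y, photons=500, bg=0.0, sigma=1.3):
    return bg + photons * _pixel_integrated_gaussian(n, x, y, sigma)


IDENTITY_CAM = CameraModel(gain=1.0, offset=0.0, read_noise=0.0)


class TestCandidates:
    def test_single_spot_found_within_one_pixel(self, rng):
        img = rng.poisson(spot_frame((64, 64), 30.3, 25.6)).astype(float)
        cands = detect_candidates(img, IDENTITY_CAM)
        assert len(cands) == 1
        assert abs(cands[0][0] - 30.3) <= 1 and abs(cands[0][1] - 25.6) <= 1

    def test_flat_frame_has_no_candidates(self, rng):
        img = rng.poisson(5.0, (64, 64)).astype(float)
        assert detect_candidates(img, IDENTITY_CAM) == []

    def test_two_separated_spots(self, rng):
        img = spot_frame((64, 64), 20.0, 32.0) + spot_frame((64, 64), 35.0, 32.0) - 5.0
        img = rng.poisson(img).astype(float)
        assert len(detect_candidates(img, IDENTITY_CAM)) == 2

    def test_even_roi_rejected(self):
        with pytest.raises(ValueError):
            detect_candidates(np.zeros((32, 32)), IDENTITY_CAM, roi_size=8)


class TestRadialSymmetry:
    def test_centered_gaussian_exact(self):
        roi = spot_roi(11, 5.0, 5.0)
        x, y = radial_symmetry_center(roi)
        assert abs(x - 5.0) < 1e-6 and abs(y - 5.0) < 1e-6

    def test_offset_gaussian_recovered(self):
        roi = spot_roi(11, 5.30, 4.80)
        x, y = radial_symmetry_center(roi)
        assert abs(x - 5.30) < 0.05 and abs(y - 4.80) < 0.05

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError):
            radial_symmetry_center(np.full((11, 11), 7.0))

    def test_agrees_with_map_on_clean_spot(self):
        roi = spot_roi(11, 5.2, 4.9, bg=3.0)
        xr, yr = radial_symmetry_center(roi)
        loc = map_refine(roi, priors=None)
        assert abs(loc.x - xr) < 0.1 and abs(loc.y - yr) < 0.1


class TestMapRefine:
    def test_noiseless_parameters_recovered(self):
        loc = map_refine(spot_roi(11, 5.3, 4.8, photons=500, bg=5.0), priors=None)
        assert loc.ok
        assert abs(loc.amplitude / 500 - 1) < 0.01
        assert abs(loc.background / 5.0 - 1) < 0.01
        assert abs(loc.x - 5.3) < 0.01 and abs(loc.y - 4.8) < 0.01

    def test_poisson_replicates_unbiased(self, rng):
        clean = spot_roi(11, 5.1, 5.0, photons=500, bg=5.0)
        est = [map_refine(rng.poisson(clean), priors="weak").amplitude for _ in range(200)]
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 500) < 3 * se

    def test_empty_roi_flagged(self):
        loc = map_refine(np.zeros((11, 11)))
        assert not loc.ok

    def test_precision_improves_with_photons(self, rng):
        """Localization RMSE decreases monotonically with photon count."""
        rmse = []
        for n_ph in (100, 300, 1000, 3000):
            clean = spot_roi(11, 5.2, 5.0, photons=n_ph, bg=5.0)
            err = []
            for _ in range(120):
                loc = map_refine(rng.poisson(clean))
                err.append((loc.x - 5.2) ** 2 + (loc.y - 5.0) ** 2)
            rmse.append(np.sqrt(np.mean(err)))
        assert all(a > b for a, b in zip(rmse, rmse[1:]))


class TestFilterLocalizations:
    @pytest.fixture
    def regions(self, ideal_mask):
        return segment_cells(None, label_mask=ideal_mask)

    def table(self, rows):
        return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "photons"])

    def test_amplitude_boundary_semantics(self, regions):
        c = regions[0].centroid
        locs = self.table([(0, c[0], c[1], 249.0), (0, c[0] + 1, c[1], 250.0)])
        out = filter_localizations(locs, regions)
        assert len(out) == 1 and out.iloc[0]["photons"] == 250.0

    def test_distance_outside_mask_boundary(self, regions):
        r = regions[0]
        ys, xs = np.nonzero(r.mask)
        x_edge = xs.max()
        y_mid = int(np.median(ys[xs == x_edge]))
        locs = self.table(
            [(0, x_edge + 3, y_mid, 500.0), (0, x_edge + 5, y_mid, 500.0)]
        )
        out = filter_localizations(locs, regions, max_outside_px=3)
        assert list(out["x_px"]) == [x_edge + 3]
        assert (out["cell"] == r.label).all()

    def test_filter_is_idempotent_subset(self, regions):
        c = regions[0].centroid
        locs = self.table(
            [(0, c[0], c[1], 300.0), (0, 2.0, 2.0, 300.0), (1, c[0], c[1], 100.0)]
        )
        once = filter_localizations(locs, regions)
        twice = filter_localizations(once, regions)
        assert once[["frame", "x_px", "photons"]].equals(twice[["frame", "x_px", "photons"]])
        assert len(once) == 1
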