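"""Per-frame single-fluorophore detection and sub-pixel localization.

The detector runs in three stages, mirroring common single-molecule
localization practice:

1. candidate finding — difference-of-Gaussians local maxima, with a
   photon-calibrated acceptance on the background-subtracted ROI sum;
2. radial-symmetry sub-pixel centring (closed form, no iteration);
3. maximum a posteriori refinement of a pixel-integrated symmetric
   Gaussian under Poisson noise, returning the position, the total
   emitter photons N, the per-pixel background b and a curvature-based
   position uncertainty.

Amplitudes are in detected photons throughout, so the downstream
250-photon acceptance filter is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import erf

from .models import CameraModel
from .segment import CellRegion, _dilated_mask
from .simulate import Movie

__all__ = [
    "Localization",
    "detect_candidates",
    "radial_symmetry_center",
    "map_refine",
    "filter_localizations",
    "detect_movie",
]


@dataclass
class Localization:
    """One detected emitter in one frame (positions in px, photons)."""

    frame: int
    x: float
    y: float
    amplitude: float  # total emitter photons
    background: float  # photons / px
    sigma: float  # fitted PSF width, px
    uncertainty: float  # curvature-based position sd, px
    cell: int | None = None
    ok: bool = True  # fit converged / non-degenerate


# ----------------------------------------------------------------------
# candidate stage


def _dog_unit_response(psf_sigma: float, s1: float, s2: float) -> float:
    """Peak DoG response of a one-photon Gaussian spot of width psf_sigma."""
    return 1.0 / (2 * np.pi * (s1**2 + psf_sigma**2)) - 1.0 / (2 * np.pi * (s2**2 + psf_sigma**2))


def detect_candidates(
    frame: np.ndarray,
    camera: CameraModel,
    psf_sigma: float = 1.3,
    threshold_photons: float = 150.0,
    prefilter_photons: float = 60.0,
    roi_size: int = 11,
    nms_px: int = 5,
) -> list[tuple[int, int, float]]:
    """Find candidate emitter pixels in one camera frame.

    The frame is converted to photons, band-passed with a difference of
    Gaussians (sigma, 2*sigma) and local maxima above a weak matched
    prefilter are collected with non-maximum suppression at ``nms_px``
    spacing (finer than the ROI, so that nearby emitters surface as
    separate candidates and can be vetoed downstream instead of silently
    contaminating a fit).  Each surviving peak is accepted when the
    background-subtracted photon sum over its ROI reaches
    ``threshold_photons`` — an amplitude estimate that stays valid for
    motion-blurred spots.  Returns (x, y, estimated photons) per
    candidate.
    """
    if roi_size < 5 or roi_size % 2 == 0:
        raise ValueError("roi_size must be odd and >= 5")
    photons = camera.to_photons(frame)
    s1, s2 = psf_sigma, 2.0 * psf_sigma
    dog = ndimage.gaussian_filter(photons, s1) - ndimage.gaussian_filter(photons, s2)
    thr = prefilter_photons * _dog_unit_response(psf_sigma, s1, s2)
    half = roi_size // 2
    maxed = ndimage.maximum_filter(dog, size=nms_px, mode="nearest")
    peaks = (dog >= maxed) & (dog > thr)
    ys, xs = np.nonzero(peaks)
    out = []
    h, w = photons.shape
    for y, x in zip(ys, xs):
        y0, y1 = max(0, y - half), min(h, y + half + 1)
        x0, x1 = max(0, x - half), min(w, x + half + 1)
        roi = photons[y0:y1, x0:x1]
        border = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
        bg = float(np.median(border))
        est = float(roi.sum() - bg * roi.size)
        if est >= threshold_photons:
            out.append((int(x), int(y), est))
    out.sort(key=lambda c: (c[1], c[0]))
    return out


# ----------------------------------------------------------------------
# radial symmetry centring


def radial_symmetry_center(roi: np.ndarray) -> tuple[float, float]:
    """Sub-pixel centre of radial symmetry of a square, odd-sided ROI.

    Intensity gradients are taken on the 2x2 mid-point lattice via
    diagonal differences; the returned point minimizes the squared
    distance to all gradient lines, weighted by gradient magnitude
    squared over distance to the intensity centroid, solved from the
    2x2 normal equations.  Raises ValueError on degenerate (e.g.
    constant) input.  Coordinates are relative to the ROI pixel grid
    (centre pixel at ((n-1)/2, (n-1)/2)).
    """
    I = np.asarray(roi, dtype=float)
    if I.ndim != 2 or I.shape[0] != I.shape[1] or I.shape[0] % 2 == 0:
        raise ValueError("roi must be square with odd side")
    n = I.shape[0]
    # mid-point grid coordinates
    m = np.arange(n - 1) + 0.5
    xm, ym = np.meshgrid(m, m)
    dIdu = I[:-1, 1:] - I[1:, :-1]  # along (+x, -y) diagonal
    dIdv = I[:-1, :-1] - I[1:, 1:]  # along (-x, -y) diagonal
    # 3x3 smoothing stabilizes the gradient field
    k = np.ones((3, 3)) / 9.0
    fdu = ndimage.convolve(dIdu, k, mode="nearest")
    fdv = ndimage.convolve(dIdv, k, mode="nearest")
    dI2 = fdu**2 + fdv**2
    s = dI2.sum()
    if s <= 0:
        raise ValueError("degenerate ROI: no intensity gradients")
    # gradient-line slope in (x, y); vertical slopes handled by clamping
    den = fdu - fdv
    num = -(fdv + fdu)
    eps = 1e-12 * max(np.abs(den).max(), 1.0)
    vertical = np.abs(den) < eps
    mgrad = np.where(vertical, 0.0, num / np.where(vertical, 1.0, den))
    mgrad = np.where(vertical, 1e9, mgrad)
    b = ym - mgrad * xm
    xc = (dI2 * xm).sum() / s
    yc = (dI2 * ym).sum() / s
    wdist = np.sqrt((xm - xc) ** 2 + (ym - yc) ** 2)
    wdist = np.maximum(wdist, 1e-6)
    wgt = dI2 / wdist
    wm = wgt / (mgrad**2 + 1.0)
    sw = wm.sum()
    smw = (mgrad * wm).sum()
    smmw = (mgrad**2 * wm).sum()
    sbw = (b * wm).sum()
    smbw = (mgrad * b * wm).sum()
    det = smw * smw - smmw * sw
    if abs(det) < 1e-12 * max(sw, 1.0) ** 2:
        raise ValueError("degenerate ROI: singular normal equations")
    x0 = (smbw * sw - smw * sbw) / det
    y0 = (smbw * smw - smmw * sbw) / det
    return float(x0), float(y0)


# ----------------------------------------------------------------------
# MAP refinement


def _pixel_integrated_gaussian(n: int, x: float, y: float, sigma: float) -> np.ndarray:
    """Pixel-integrated unit symmetric Gaussian on an n x n ROI grid."""
    e = np.arange(n + 1) - 0.5
    fx = 0.5 * (erf((e[1:] - x) / (np.sqrt(2) * sigma)) - erf((e[:-1] - x) / (np.sqrt(2) * sigma)))
    fy = 0.5 * (erf((e[1:] - y) / (np.sqrt(2) * sigma)) - erf((e[:-1] - y) / (np.sqrt(2) * sigma)))
    return np.outer(fy, fx)


def map_refine(
    roi: np.ndarray,
    camera: CameraModel | None = None,
    psf_sigma: float = 1.3,
    init_center: tuple[float, float] | None = None,
    frame: int = 0,
    priors: str | None = "weak",
    prior_scale_amp: float = 1.0,
    prior_scale_sigma: float = 0.4,
    max_iter: int = 120,
) -> Localization:
    """Refine one ROI by MAP fitting of mu = b + N * G(x, y, sigma).

    ``G`` is the pixel-integrated symmetric Gaussian (summing to 1 over
    the plane) and the likelihood is Poisson per pixel.  Weak log-normal
    priors centred on the candidate-stage estimates keep degenerate fits
    bounded; with ``priors=None`` the fit is pure maximum likelihood.
    The ROI is given in camera ADU when ``camera`` is supplied, photons
    otherwise.  Non-converged or degenerate fits are returned flagged
    (``ok=False``) and are excluded downstream.
    """
    roi = np.asarray(roi, dtype=float)
    n = roi.shape[0]
    photons = camera.to_photons(roi) if camera is not None else np.clip(roi, 0.0, None)
    border = np.concatenate(
        [photons[0], photons[-1], photons[1:-1, 0], photons[1:-1, -1]]
    )
    b0 = max(float(np.median(border)), 1e-3)
    n0 = max(float(photons.sum() - b0 * photons.size), 1.0)
    c = (n - 1) / 2.0
    if init_center is None:
        try:
            init_center = radial_symmetry_center(photons)
        except ValueError:
            init_center = (c, c)
    x0, y0 = init_center
    if photons.sum() <= 0:
        return Localization(frame, x0, y0, 0.0, 0.0, psf_sigma, np.inf, ok=False)

    logn0, logb0, logs0 = np.log(n0), np.log(b0), np.log(psf_sigma)

    def nll(p):
        x, y, ln, lb, ls = p
        N, b, s = np.exp(ln), np.exp(lb), np.exp(ls)
        mu = b + N * _pixel_integrated_gaussian(n, x, y, s)
        mu = np.maximum(mu, 1e-12)
        val = float((mu - photons * np.log(mu)).sum())
        if priors == "weak":
            val += 0.5 * ((ln - logn0) / prior_scale_amp) ** 2
            val += 0.5 * ((lb - logb0) / prior_scale_amp) ** 2
            val += 0.5 * ((ls - logs0) / prior_scale_sigma) ** 2
        return val

    p0 = np.array([x0, y0, logn0, logb0, logs0])
    half = n / 2.0
    bounds = [
        (c - half, c + half),
        (c - half, c + half),
        (logn0 - 6, logn0 + 6),
        (logb0 - 6, logb0 + 6),
        (logs0 - 2.5, logs0 + 2.5),
    ]
    res = optimize.minimize(
        nll, p0, method="L-BFGS-B", bounds=bounds, options={"maxiter": max_iter}
    )
    x, y, ln, lb, ls = res.x
    N, b, s = float(np.exp(ln)), float(np.exp(lb)), float(np.exp(ls))
    ok = bool(res.success or res.status == 1)
    # curvature-based position uncertainty from a numeric 2x2 Hessian
    unc = np.inf
    if ok:
        h = 1e-3
        f0 = nll(res.x)

        def shift(dx, dy):
            p = res.x.copy()
            p[0] += dx
            p[1] += dy
            return nll(p)

        hxx = (shift(h, 0) - 2 * f0 + shift(-h, 0)) / h**2
        hyy = (shift(0, h) - 2 * f0 + shift(0, -h)) / h**2
        if hxx > 0 and hyy > 0:
            unc = float(np.sqrt(0.5 * (1.0 / hxx + 1.0 / hyy)))
        else:
            ok = False
    return Localization(frame, float(x), float(y), N, b, s, unc, ok=ok)


# ----------------------------------------------------------------------
# movie-level driver and filters


def detect_movie(
    movie: Movie,
    psf_sigma: float = 1.3,
    threshold_photons: float = 150.0,
    roi_size: int = 11,
    priors: str | None = "weak",
    pair_exclusion_px: float = 10.0,
) -> pd.DataFrame:
    """Detect and refine localizations in every frame of a movie.

    Candidates closer than ``pair_exclusion_px`` to another candidate in
    the same frame are discarded before fitting: their ROIs overlap, and
    the single-emitter model would return a position pulled toward the
    neighbour (multi-emitter fitting is out of scope, so rejection is the
    conservative treatment).  Returns a localization table with columns
    frame, x_px, y_px, photons, background, sigma_px, uncertainty_px.
    """
    half = roi_size // 2
    rows = []
    h, w = movie.data.shape[1:]
    for f in range(movie.n_frames):
        frame = movie.data[f]
        cands = detect_candidates(
            frame, movie.camera, psf_sigma, threshold_photons, roi_size=roi_size
        )
        if len(cands) > 1:
            xy = np.array([(c[0], c[1]) for c in cands], dtype=float)
            d = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
            np.fill_diagonal(d, np.inf)
            cands = [c for c, dmin in zip(cands, d.min(axis=1)) if dmin > pair_exclusion_px]
        for cx, cy, _ in cands:
            if not (half <= cx < w - half and half <= cy < h - half):
                continue
            roi = frame[cy - half : cy + half + 1, cx - half : cx + half + 1]
            loc = map_refine(roi, movie.camera, psf_sigma, frame=f, priors=priors)
            if not loc.ok:
                continue
            rows.append(
                (
                    f,
                    loc.x + cx - half,
                    loc.y + cy - half,
                    loc.amplitude,
                    loc.background,
                    loc.sigma,
                    loc.uncertainty,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["frame", "x_px", "y_px", "photons", "background", "sigma_px", "uncertainty_px"],
    )


def filter_localizations(
    locs: pd.DataFrame,
    regions: list[CellRegion],
    min_photons: float = 250.0,
    max_outside_px: int = 3,
) -> pd.DataFrame:
    """Apply the amplitude and cell-proximity acceptance filters.

    Keeps localizations with ``photons >= min_photons`` that fall within
    some region mask dilated by ``max_outside_px`` (Chebyshev distance via
    binary dilation), and assigns each survivor the nearest region label.
    The operation is a pure filter: output rows are a subset of input.
    """
    if locs.empty:
        out = locs.copy()
        out["cell"] = pd.Series(dtype=int)
        return out
    keep_amp = locs["photons"].to_numpy() >= min_photons
    if not regions:
        out = locs[np.zeros(len(locs), dtype=bool)].copy()
        out["cell"] = pd.Series(dtype=int)
        return out
    shape = regions[0].mask.shape
    label_img = np.zeros(shape, dtype=np.int32)
    for r in regions:
        label_img[r.mask & (label_img == 0)] = r.label
    # nearest region label everywhere (for assignment)
    _, (iy, ix) = ndimage.distance_transform_edt(label_img == 0, return_indices=True)
    nearest = label_img[iy, ix]
    allowed = np.zeros(shape, dtype=bool)
    for r in regions:
        allowed |= _dilated_mask(r, max_outside_px)
    xi = np.clip(np.rint(locs["x_px"].to_numpy()).astype(int), 0, shape[1] - 1)
    yi = np.clip(np.rint(locs["y_px"].to_numpy()).astype(int), 0, shape[0] - 1)
    inside = allowed[yi, xi]
    keep = keep_amp & inside
    out = locs[keep].copy()
    out["cell"] = nearest[yi[keep], xi[keep]]
    return out.reset_index(drop=True)
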