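"""Synthetic stroboscopic fluorescence movies with ground truth.

The generator emulates the statistical structure of live-cell
single-molecule tracking data in rod-shaped bacteria:

* micro-colonies of 1-8 spherocylindrical cells on a uniform background,
* molecules switching among up to three diffusive states by a Markov
  process, confined by reflecting cell boundaries,
* stroboscopic excitation (a short laser pulse inside each camera
  exposure) with motion blur over the pulse window,
* Gaussian PSF, Poisson photon statistics, photobleaching and short
  blinking dark states, and a Poisson + Gaussian (sCMOS-like) camera.

Every movie is accompanied by a ground-truth localization table so the
whole downstream analysis can be validated without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .models import CameraModel, DiffusionModel

__all__ = [
    "DEFAULT_PIXEL_SIZE_NM",
    "Movie",
    "TrueTrajectory",
    "make_colony",
    "simulate_states",
    "simulate_trajectory",
    "render_movie",
    "simulate_movie",
]

#: Default pixel size in the sample plane (nm/px): 1314 nm per 20 px.
DEFAULT_PIXEL_SIZE_NM = 65.7


@dataclass
class Movie:
    """A rendered movie: (T, H, W) camera frames plus acquisition metadata."""

    data: np.ndarray  # uint16 ADU, shape (T, H, W)
    pixel_size_nm: float
    frame_time_s: float
    pulse_time_s: float
    camera: CameraModel

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def photons(self) -> np.ndarray:
        return self.camera.to_photons(self.data)


@dataclass
class TrueTrajectory:
    """Ground truth for one molecule.

    Positions are recorded on the simulation sub-step grid; frame-level
    truth (the photon-weighted mean position over the pulse window) is
    produced by :func:`render_movie`.
    """

    molecule: int
    cell: int
    geometry: CellGeometry
    start_frame: int
    positions: np.ndarray  # (n_frames, n_substeps, 3) um, pulse-window sub-steps
    states: np.ndarray  # (n_frames,) state index per frame
    alive: np.ndarray  # (n_frames,) photo-active (not yet bleached)
    emitting: np.ndarray  # (n_frames,) alive and not in a blinking dark state

    @property
    def n_frames(self) -> int:
        return len(self.states)


# ----------------------------------------------------------------------
# colony construction


def _capsule_distance_2d(g1: CellGeometry, g2: CellGeometry) -> float:
    """Minimum distance between the two projected capsule outlines."""
    p1, q1 = (e[:2] for e in g1.axis_endpoints())
    p2, q2 = (e[:2] for e in g2.axis_endpoints())
    d = _segment_segment_distance(p1, q1, p2, q2)
    return d - g1.radius - g2.radius


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    # standard closest-approach of two 2D segments
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e_, f = d1 @ d1, d2 @ d2, d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e_ - b * b
    s = np.clip((b * f - c * e_) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = (b * s + f) / e_ if e_ > 1e-12 else 0.0
    t = np.clip(t, 0, 1)
    s = np.clip((b * t - c) / a, 0, 1) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def make_colony(
    n_cells: int,
    rng: np.random.Generator | int,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    length_range: tuple[float, float] = (2.8, 3.8),
    radius_range: tuple[float, float] = (0.45, 0.55),
    min_gap_um: float = 0.08,
    max_tries: int = 2000,
) -> tuple[list[CellGeometry], np.ndarray]:
    """Place ``n_cells`` non-overlapping cells and rasterize a label mask.

    Returns the cell geometries (um coordinates, origin at the centre of
    pixel (0, 0)) and a 16-bit label image where label ``i+1`` marks cell
    ``i``.  Raises ``RuntimeError`` if a non-overlapping placement cannot
    be found within ``max_tries`` attempts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng)
    px = pixel_size_nm / 1000.0
    h, w = image_shape
    fov_w, fov_h = w * px, h * px
    margin = max(length_range[1] / 2.0 + 0.3, 1.0)
    cells: list[CellGeometry] = []
    tries = 0
    # first cell near the centre, later cells clustered around it
    while len(cells) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in the field of view"
            )
        tries += 1
        length = rng.uniform(*length_range)
        radius = rng.uniform(*radius_range)
        if not cells:
            cx = fov_w / 2.0 + rng.uniform(-0.5, 0.5)
            cy = fov_h / 2.0 + rng.uniform(-0.5, 0.5)
        else:
            anchor = cells[rng.integers(len(cells))]
            ang = rng.uniform(0, 2 * np.pi)
            dist = anchor.radius + radius + rng.uniform(min_gap_um, 0.8)
            cx = anchor.center[0] + dist * np.cos(ang) * rng.uniform(1.0, 2.5)
            cy = anchor.center[1] + dist * np.sin(ang) * rng.uniform(1.0, 2.5)
        if not (margin < cx < fov_w - margin and margin < cy < fov_h - margin):
            continue
        cand = CellGeometry((cx, cy), rng.uniform(0, np.pi), length, radius)
        if all(_capsule_distance_2d(cand, c) > min_gap_um for c in cells):
            cells.append(cand)
    mask = rasterize_labels(cells, image_shape, pixel_size_nm)
    return cells, mask


def rasterize_labels(
    cells: list[CellGeometry],
    image_shape: tuple[int, int],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> np.ndarray:
    """16-bit label image of the projected cell outlines (pixel centres)."""
    px = pixel_size_nm / 1000.0
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel() * px, yy.ravel() * px])
    mask = np.zeros(h * w, dtype=np.uint16)
    for i, cell in enumerate(cells):
        inside = cell.contains_2d(pts)
        mask[inside & (mask == 0)] = i + 1
    return mask.reshape(h, w)


# ----------------------------------------------------------------------
# state and position dynamics


def simulate_states(model: DiffusionModel, n_steps: int, rng: np.random.Generator | int) -> np.ndarray:
    """Realize the per-frame Markov state chain (initial state from ``w``)."""
    rng = np.random.default_rng(rng)
    if model.K > 1 and model.A is None:
        raise ValueError("a transition matrix A is required for K > 1")
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.choice(model.K, p=model.w)
    if model.K == 1:
        states[:] = 0
        return states
    cum = np.cumsum(model.A, axis=1)
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states


def simulate_trajectory(
    geometry: CellGeometry,
    model: DiffusionModel,
    n_frames: int,
    frame_time_s: float,
    pulse_time_s: float | None = None,
    substeps: int = 10,
    bleach_rate: float = 0.0,
    blink_prob: float = 0.0,
    max_dark_frames: int = 2,
    confined: bool = True,
    rng: np.random.Generator | int = 0,
    molecule: int = 0,
    cell: int = 0,
    start_frame: int = 0,
) -> TrueTrajectory:
    """Simulate one confined Brownian molecule over ``n_frames`` frames.

    Within each frame the molecule takes ``substeps`` Brownian sub-steps
    spanning the excitation pulse (for motion blur) followed by coarser
    dark-interval steps up to the next frame.  The diffusive state is
    constant within a frame and switches between frames via ``model.A``;
    when no transition matrix is given the molecule keeps the state drawn
    from ``w`` at birth.  Bleaching is geometric with per-frame survival
    ``exp(-bleach_rate * pulse_time)`` (bleaching occurs under
    illumination); blinking enters a dark state of 1..``max_dark_frames``
    frames with probability ``blink_prob`` per live frame.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if frame_time_s <= 0:
        raise ValueError("frame_time_s must be positive")
    rng = np.random.default_rng(rng)
    if pulse_time_s is None:
        pulse_time_s = frame_time_s
    if pulse_time_s > frame_time_s:
        raise ValueError("pulse_time_s cannot exceed frame_time_s")

    # photobleaching first: survive each illuminated frame with probability
    # exp(-k * t_pulse); frames after the bleach carry no signal, so the
    # walk is only simulated while the fluorophore is photo-active.
    n_sim = n_frames
    if bleach_rate > 0:
        q = -np.expm1(-bleach_rate * pulse_time_s)  # per-frame bleach prob
        n_sim = min(n_frames, int(rng.geometric(q)))

    if model.A is not None:
        states = simulate_states(model, n_sim, rng)
    else:
        states = np.full(n_sim, rng.choice(model.K, p=model.w), dtype=np.int64)

    pos = geometry.sample_volume(1, rng)[0]
    if not geometry.contains(pos):
        raise ValueError("initial position outside the cell geometry")

    dt_pulse = pulse_time_s / substeps
    dark = frame_time_s - pulse_time_s
    n_dark = 0 if dark <= 0 else max(1, int(np.ceil(dark / dt_pulse / 4.0)))
    dt_dark = dark / n_dark if n_dark else 0.0
    per_frame = substeps + n_dark

    # pre-drawn standard-normal increments, scaled per frame by the state
    incs = rng.standard_normal((n_sim * per_frame, 3))
    sig = np.empty(n_sim * per_frame)
    sp = np.sqrt(2.0 * model.D[states] * dt_pulse)
    sd = np.sqrt(2.0 * model.D[states] * dt_dark) if n_dark else None
    for f in range(n_sim):
        sig[f * per_frame : f * per_frame + substeps] = sp[f]
        if n_dark:
            sig[f * per_frame + substeps : (f + 1) * per_frame] = sd[f]
    incs *= sig[:, None]

    # fast scalar walk with specular reflection at the spherocylinder
    import math

    cx, cy = geometry.center
    ux, uy = math.cos(geometry.orientation), math.sin(geometry.orientation)
    hlen = geometry.axis_half_length
    r = geometry.radius
    x, y, z = float(pos[0]), float(pos[1]), float(pos[2])
    positions = np.empty((n_sim, substeps, 3))
    k = 0
    for f in range(n_sim):
        for i in range(per_frame):
            if i < substeps:
                positions[f, i, 0] = x
                positions[f, i, 1] = y
                positions[f, i, 2] = z
            x += incs[k, 0]
            y += incs[k, 1]
            z += incs[k, 2]
            k += 1
            if confined:
                for _ in range(8):
                    t = (x - cx) * ux + (y - cy) * uy
                    t = -hlen if t < -hlen else (hlen if t > hlen else t)
                    fx = cx + t * ux
                    fy = cy + t * uy
                    dx, dy = x - fx, y - fy
                    d = math.sqrt(dx * dx + dy * dy + z * z)
                    if d <= r:
                        break
                    fac = 2.0 * (d - r) / d
                    x -= fac * dx
                    y -= fac * dy
                    z -= fac * z
                else:  # pathological deep excursion: clamp just inside
                    fac = r * (1.0 - 1e-12) / d
                    x, y, z = fx + fac * dx, fy + fac * dy, fac * z

    n_frames = n_sim
    alive = np.ones(n_frames, dtype=bool)
    emitting = alive.copy()
    if blink_prob > 0:
        f = 0
        while f < n_frames:
            if emitting[f] and rng.random() < blink_prob:
                dur = int(rng.integers(1, max_dark_frames + 1))
                emitting[f : f + dur] = False
                f += dur
            f += 1
    return TrueTrajectory(
        molecule=molecule,
        cell=cell,
        geometry=geometry,
        start_frame=start_frame,
        positions=positions,
        states=states,
        alive=alive,
        emitting=emitting,
    )


# ----------------------------------------------------------------------
# rendering


def render_movie(
    trajectories: list[TrueTrajectory],
    geometries: list[CellGeometry],
    n_frames: int,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    psf_sigma_px: float = 1.3,
    photons_per_pulse: float = 500.0,
    background: float = 5.0,
    cell_background: float = 3.0,
    camera: CameraModel = CameraModel(),
    frame_time_s: float = 0.005,
    pulse_time_s: float = 0.003,
    rng: np.random.Generator | int = 0,
    label_mask: np.ndarray | None = None,
) -> tuple[Movie, pd.DataFrame]:
    """Render camera frames from true trajectories.

    Photons are emitted only during the excitation pulse: each detected
    photon is attributed to a uniformly chosen pulse sub-step position
    (motion blur) and scattered by the Gaussian PSF before being binned
    into pixels, so with unit gain and no noise the image integral equals
    the emitted photon count exactly.  ``background`` is a uniform photon
    rate per pixel per frame; ``cell_background`` adds cellular
    autofluorescence inside the label mask.  The returned truth table
    holds the photon-weighted mean emitter position per frame.
    """
    if pulse_time_s > frame_time_s:
        raise ValueError("pulse_time_s cannot exceed frame_time_s")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    rng = np.random.default_rng(rng)
    px = pixel_size_nm / 1000.0
    h, w = image_shape
    if label_mask is None:
        label_mask = rasterize_labels(geometries, image_shape, pixel_size_nm)

    bg_rate = np.full((h, w), float(background))
    if cell_background:
        bg_rate += cell_background * (label_mask > 0)

    edges_y = np.arange(h + 1) - 0.5
    edges_x = np.arange(w + 1) - 0.5
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    truth_rows: list[tuple] = []
    for f in range(n_frames):
        signal = np.zeros((h, w))
        for tr in trajectories:
            lf = f - tr.start_frame
            if lf < 0 or lf >= tr.n_frames or not tr.emitting[lf]:
                continue
            n_ph = rng.poisson(photons_per_pulse)
            if n_ph == 0:
                continue
            sub = tr.positions[lf]  # (substeps, 3)
            idx = rng.integers(0, sub.shape[0], n_ph)
            xy = sub[idx, :2] / px  # pixel units
            xy = xy + rng.normal(0.0, psf_sigma_px, (n_ph, 2))
            hist, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(edges_y, edges_x))
            signal += hist
            # truth: photon-weighted mean of the source sub-step positions
            mean_xy = sub[idx, :2].mean(axis=0) / px
            truth_rows.append(
                (f, tr.molecule, tr.cell, mean_xy[0], mean_xy[1], int(tr.states[lf]), n_ph)
            )
        # the per-photon binning already realizes the signal's Poisson
        # statistics; only the background rate remains to be drawn
        counts = signal + rng.poisson(bg_rate)
        adu = camera.offset + camera.gain * counts
        if camera.read_noise > 0:
            adu = adu + rng.normal(0.0, camera.read_noise, (h, w))
        frames[f] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)
    movie = Movie(frames, pixel_size_nm, frame_time_s, pulse_time_s, camera)
    truth = pd.DataFrame(
        truth_rows, columns=["frame", "molecule", "cell", "x_px", "y_px", "state", "photons"]
    )
    return movie, truth


# ----------------------------------------------------------------------
# high-level movie generator


def simulate_movie(
    model: DiffusionModel,
    n_cells: int = 3,
    n_frames: int = 500,
    molecules_per_cell: int = 25,
    frame_time_s: float = 0.005,
    pulse_time_s: float = 0.003,
    photons_per_pulse: float = 500.0,
    background: float = 5.0,
    cell_background: float = 3.0,
    bleach_rate: float = 11.0,
    blink_prob: float = 0.05,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    psf_sigma_px: float = 1.3,
    camera: CameraModel = CameraModel(),
    substeps: int = 10,
    rng: np.random.Generator | int = 0,
) -> tuple[Movie, np.ndarray, pd.DataFrame, list[TrueTrajectory]]:
    """One synthetic acquisition: colony, staggered molecules, rendering.

    Molecules activate at frames drawn uniformly over the movie so the
    emitter density stays sparse (roughly ``molecules_per_cell *
    mean_on_frames / n_frames`` active per cell per frame), mimicking
    sparse photo-activation / labelling.  Returns the movie, the label
    mask, the ground-truth localization table and the true trajectories.
    """
    rng = np.random.default_rng(rng)
    cells, mask = make_colony(n_cells, rng, image_shape, pixel_size_nm)
    trajs: list[TrueTrajectory] = []
    mol = 0
    for ci, cell in enumerate(cells):
        starts = np.sort(rng.integers(0, n_frames, molecules_per_cell))
        for s in starts:
            tr = simulate_trajectory(
                cell,
                model,
                n_frames=n_frames - int(s),
                frame_time_s=frame_time_s,
                pulse_time_s=pulse_time_s,
                substeps=substeps,
                bleach_rate=bleach_rate,
                blink_prob=blink_prob,
                rng=rng,
                molecule=mol,
                cell=ci + 1,
                start_frame=int(s),
            )
            trajs.append(tr)
            mol += 1
    movie, truth = render_movie(
        trajs,
        cells,
        n_frames=n_frames,
        image_shape=image_shape,
        pixel_size_nm=pixel_size_nm,
        psf_sigma_px=psf_sigma_px,
        photons_per_pulse=photons_per_pulse,
        background=background,
        cell_background=cell_background,
        camera=camera,
        frame_time_s=frame_time_s,
        pulse_time_s=pulse_time_s,
        rng=rng,
        label_mask=mask,
    )
    return movie, mask, truth, trajs
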