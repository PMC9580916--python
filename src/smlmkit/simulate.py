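"""Synthetic SMLM data with ground truth.

Generates movies of blinking emitters (two-state Markov on/off kinetics,
pixel-integrated Gaussian PSFs, Poisson photon noise, Gaussian read noise,
inhomogeneous slowly-drifting background), Brownian trajectories for
tracking analysis, two-channel nanoruler scenes for chromatic calibration,
and bright fiducial localization traces — each paired with the ground truth
needed for parameter-recovery tests.

All outputs are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .core_io import AffineTransform2D, DriftTrace, LocalizationTable, Movie

__all__ = [
    "EmitterModel",
    "NoiseModel",
    "GroundTruth",
    "simulate_movie",
    "simulate_tracks",
    "simulate_nanoruler_pairs",
    "simulate_fiducial_table",
    "simulate_filament_table",
    "make_smooth_drift",
]


@dataclass
class EmitterModel:
    """Blinking point emitters with a Gaussian PSF.

    ``k_on`` / ``k_off`` are per-frame switching probabilities of the
    two-state Markov chain (SMLM blinking is equilibrated towards the off
    state, i.e. ``k_on << k_off`` for realistic scenes).  ``photons_per_frame``
    is the mean photon count emitted while on.
    """

    positions: np.ndarray  # (n, 2) true (x, y) in px
    k_on: float = 0.02
    k_off: float = 0.5
    photons_per_frame: float = 2000.0
    psf_sigma_px: float = 1.3
    initial_on_fraction: float | None = None  # default: equilibrium k_on/(k_on+k_off)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if not (0.0 <= self.k_on <= 1.0 and 0.0 <= self.k_off <= 1.0):
            raise ValueError("k_on, k_off must be in [0, 1]")
        if not self.photons_per_frame > 0:
            raise ValueError("photons_per_frame must be > 0")
        if not self.psf_sigma_px > 0:
            raise ValueError("psf_sigma_px must be > 0")


@dataclass
class NoiseModel:
    """Camera background/noise: constant offset + linear spatial gradient,
    slow temporal background drift, Poisson shot noise, Gaussian read noise.

    EMCCD excess noise is deliberately not modelled (plain Poisson + read
    noise); see the methods note.
    """

    background_offset: float = 20.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # counts/px in (x, y)
    background_drift_per_frame: float = 0.0
    read_noise_sigma: float = 1.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.background_offset < 0 or self.read_noise_sigma < 0:
            raise ValueError("background_offset and read_noise_sigma must be >= 0")

    def background_field(self, shape: tuple[int, int], frame: int) -> np.ndarray:
        rows, cols = shape
        # pixel centers at (col+0.5, row+0.5)
        xg, yg = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
        gx, gy = self.background_gradient
        bg = self.background_offset + gx * xg + gy * yg + self.background_drift_per_frame * frame
        return np.clip(bg, 0.0, None)


@dataclass
class GroundTruth:
    """Everything the simulator knows: per-frame on/off states, true
    (drifted) emission positions, true drift, true chromatic transform,
    true trajectories and per-population diffusion coefficients."""

    positions: np.ndarray | None = None          # (n_emitters, 2) static true positions, px
    states: np.ndarray | None = None             # (n_frames, n_emitters) bool on/off
    emissions: pd.DataFrame | None = None        # one row per rendered emission
    drift: DriftTrace | None = None
    transform: AffineTransform2D | None = None
    tracks: pd.DataFrame | None = None           # true trajectories incl. blinked-out frames
    diffusion_coefficients: np.ndarray | None = None  # per population, px^2/frame
    population_of_track: np.ndarray | None = None
    site_pairs: pd.DataFrame | None = None       # nanoruler site pairing
    collinear_sites: bool = False


def _integrated_psf(x0: float, y0: float, sigma: float, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Gaussian PSF integrated over pixel areas (difference of CDFs at pixel
    edges), for pixels with row indices ``rows`` and column indices ``cols``.
    Returns the fraction of total photons falling in each pixel."""
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 1 - x0) / s) - erf((cols - x0) / s))
    fy = 0.5 * (erf((rows + 1 - y0) / s) - erf((rows - y0) / s))
    return np.outer(fy, fx)


def simulate_movie(
    emitters: EmitterModel | Sequence[EmitterModel],
    noise: NoiseModel,
    drift: DriftTrace | None,
    n_frames: int,
    shape: tuple[int, int],
    seed: int,
) -> tuple[Movie, GroundTruth]:
    """Render a synthetic SMLM movie plus its ground truth.

    Each on-state emitter contributes a pixel-integrated 2D Gaussian PSF
    whose photons are Poisson sampled (when ``noise.poisson``); background
    and Gaussian read noise are added on top; drift displaces the true
    positions frame by frame.  Emitters whose PSF center leaves the field
    after drift are clipped and flagged in the truth table.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    models = [emitters] if isinstance(emitters, EmitterModel) else list(emitters)
    rng = np.random.default_rng(seed)
    rows_n, cols_n = shape
    data = np.zeros((n_frames, rows_n, cols_n), dtype=np.float64)

    n_total = sum(len(m.positions) for m in models)
    states = np.zeros((n_frames, n_total), dtype=bool)
    emission_rows: list[tuple] = []

    # Pre-draw blinking chains per model
    offset = 0
    chains: list[np.ndarray] = []
    for m in models:
        n_em = len(m.positions)
        p0 = m.initial_on_fraction
        if p0 is None:
            tot = m.k_on + m.k_off
            p0 = m.k_on / tot if tot > 0 else 0.0
        on = rng.random(n_em) < p0
        chain = np.zeros((n_frames, n_em), dtype=bool)
        for t in range(n_frames):
            chain[t] = on
            u = rng.random(n_em)
            on = np.where(on, u >= m.k_off, u < m.k_on)
        chains.append(chain)
        states[:, offset:offset + n_em] = chain
        offset += n_em

    for t in range(n_frames):
        frame = noise.background_field(shape, t).copy()
        if noise.poisson:
            frame = rng.poisson(frame).astype(np.float64)
        offset = 0
        for m, chain in zip(models, chains):
            for j, (x0, y0) in enumerate(m.positions):
                if not chain[t, j]:
                    continue
                xd, yd = x0, y0
                if drift is not None:
                    xd, yd = x0 + drift.dx[t], y0 + drift.dy[t]
                clipped = not (0.0 <= xd < cols_n and 0.0 <= yd < rows_n)
                # restrict to a 5-sigma window for speed
                r = int(np.ceil(5 * m.psf_sigma_px))
                c0, c1 = int(np.floor(xd)) - r, int(np.floor(xd)) + r + 1
                r0, r1 = int(np.floor(yd)) - r, int(np.floor(yd)) + r + 1
                c0, c1 = max(c0, 0), min(c1, cols_n)
                r0, r1 = max(r0, 0), min(r1, rows_n)
                photons = 0.0
                if c1 > c0 and r1 > r0:
                    w = _integrated_psf(xd, yd, m.psf_sigma_px, np.arange(r0, r1), np.arange(c0, c1))
                    mean = m.photons_per_frame * w
                    signal = rng.poisson(mean).astype(np.float64) if noise.poisson else mean
                    frame[r0:r1, c0:c1] += signal
                    photons = float(signal.sum())
                emission_rows.append((t, offset + j, xd, yd, photons, clipped))
            offset += len(m.positions)
        if noise.read_noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise.read_noise_sigma, size=frame.shape)
        data[t] = np.clip(frame, 0.0, None)

    emissions = pd.DataFrame(
        emission_rows, columns=["frame", "emitter", "x_true", "y_true", "photons", "clipped"]
    )
    truth = GroundTruth(
        positions=np.vstack([m.positions for m in models]),
        states=states,
        emissions=emissions,
        drift=drift,
    )
    return Movie(data), truth


def simulate_tracks(
    n_particles: int,
    D_list: Sequence[float],
    fractions: Sequence[float],
    n_frames: int,
    p_blink: float = 0.0,
    sigma_loc: float = 0.0,
    seed: int = 0,
    box_size_px: float = 64.0,
    frame_interval: float = 1.0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate 2D Brownian trajectories from one or more diffusive populations.

    Per-axis increments per frame step are ``Normal(0, sqrt(2 * D * tau))``
    with ``tau = frame_interval`` (default one frame, so D is in px^2/frame).
    Optional per-axis localization noise ``sigma_loc`` is added to the
    observed positions; blinking removes individual frames with probability
    ``p_blink``.  The truth records population membership and the noise-free
    trajectories.
    """
    D_list = np.asarray(D_list, dtype=np.float64)
    fractions = np.asarray(fractions, dtype=np.float64)
    if D_list.size == 0:
        raise ValueError("D_list must be non-empty")
    if (D_list <= 0).any():
        raise ValueError("all diffusion coefficients must be > 0")
    if D_list.shape != fractions.shape or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must match D_list and sum to 1")

    rng = np.random.default_rng(seed)
    pop = rng.choice(len(D_list), size=n_particles, p=fractions)
    start = rng.uniform(0.0, box_size_px, size=(n_particles, 2))
    sd = np.sqrt(2.0 * D_list[pop] * frame_interval)  # per-axis step std per particle
    steps = rng.normal(0.0, 1.0, size=(n_particles, n_frames - 1, 2)) * sd[:, None, None]
    paths = np.concatenate([start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)

    visible = rng.random((n_particles, n_frames)) >= p_blink
    obs = paths + rng.normal(0.0, sigma_loc, size=paths.shape) if sigma_loc > 0 else paths

    pid, t = np.nonzero(visible)
    df = pd.DataFrame(
        {
            "frame": t,
            "x": obs[pid, t, 0],
            "y": obs[pid, t, 1],
            "intensity": 1000.0,
            "track_id": pid,
            "channel": 0,
        }
    ).sort_values(["frame", "track_id"], kind="stable")
    table = LocalizationTable(df, frame_interval_s=frame_interval)

    tracks = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_particles), n_frames),
            "frame": np.tile(np.arange(n_frames), n_particles),
            "x_true": paths[:, :, 0].ravel(),
            "y_true": paths[:, :, 1].ravel(),
            "visible": visible.ravel(),
        }
    )
    truth = GroundTruth(
        tracks=tracks,
        diffusion_coefficients=D_list,
        population_of_track=pop,
    )
    return table, truth


def simulate_nanoruler_pairs(
    n_sites: int,
    spacing_nm: float,
    transform: AffineTransform2D,
    sigma_loc: float,
    n_locs_per_site: int,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
    field_px: float = 32.0,
    collinear: bool = False,
) -> tuple[LocalizationTable, GroundTruth]:
    """Two-channel DNA-PAINT nanoruler scene for chromatic calibration.

    Docking sites come in closely spaced pairs (``spacing_nm`` apart along a
    random orientation).  Channel 0 observes the true sites; channel 1
    observes ``transform(sites)``; both with i.i.d. per-axis noise
    ``sigma_loc`` (px) on each of ``n_locs_per_site`` repeated localizations.
    With ``collinear=True`` all sites fall on one line (degenerate design for
    affine estimation), flagged in the truth.
    """
    if n_sites < 3:
        raise ValueError("n_sites must be >= 3 for downstream affine estimation")
    rng = np.random.default_rng(seed)
    spacing_px = spacing_nm / pixel_size_nm
    if collinear:
        s = rng.uniform(0.1, 0.9, size=n_sites) * field_px
        anchors = np.column_stack([s, 0.4 * s + 1.0])
        # pair offsets along the line so every site stays exactly collinear
        theta = np.full(n_sites, np.arctan2(0.4, 1.0))
    else:
        anchors = rng.uniform(0.15 * field_px, 0.85 * field_px, size=(n_sites, 2))
        theta = rng.uniform(0, 2 * np.pi, size=n_sites)
    offset = 0.5 * spacing_px * np.column_stack([np.cos(theta), np.sin(theta)])
    sites = np.vstack([anchors - offset, anchors + offset])  # (2*n_sites, 2)

    ch1_sites = sites
    ch2_sites = transform.apply(sites)
    frames, xs, ys, chans, site_ids = [], [], [], [], []
    for ch, pts in ((0, ch1_sites), (1, ch2_sites)):
        for k, (sx, sy) in enumerate(pts):
            noise = rng.normal(0.0, sigma_loc, size=(n_locs_per_site, 2)) if sigma_loc > 0 else np.zeros((n_locs_per_site, 2))
            xs.extend(sx + noise[:, 0])
            ys.extend(sy + noise[:, 1])
            frames.extend(range(n_locs_per_site))
            chans.extend([ch] * n_locs_per_site)
            site_ids.extend([k] * n_locs_per_site)
    table = LocalizationTable.from_arrays(
        frame=frames, x=xs, y=ys, intensity=np.full(len(xs), 1000.0),
        channel=chans, pixel_size_nm=pixel_size_nm,
    )
    pairs = pd.DataFrame(
        {
            "site": np.arange(len(sites)),
            "x_ch1": ch1_sites[:, 0], "y_ch1": ch1_sites[:, 1],
            "x_ch2": ch2_sites[:, 0], "y_ch2": ch2_sites[:, 1],
        }
    )
    truth = GroundTruth(transform=transform, site_pairs=pairs, collinear_sites=collinear)
    # carry per-row site id for tests
    df = table.df.copy()
    df["site"] = -1
    table.df["channel"] = chans  # already set; keep canonical shape
    truth.emissions = pd.DataFrame({"site": site_ids, "channel": chans})
    return table, truth


def simulate_fiducial_table(
    positions: Sequence[Sequence[float]],
    n_frames: int,
    drift: DriftTrace | None,
    sigma_loc: float,
    intensity: float = 50000.0,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
) -> LocalizationTable:
    """Localization table of stable bright fiducial markers.

    One localization per marker per frame, at the drifted true position plus
    i.i.d. per-axis Gaussian noise ``sigma_loc`` (px).
    """
    rng = np.random.default_rng(seed)
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    n = len(positions)
    t = np.tile(np.arange(n_frames), n)
    fid = np.repeat(np.arange(n), n_frames)
    x = positions[fid, 0] + (drift.dx[t] if drift is not None else 0.0)
    y = positions[fid, 1] + (drift.dy[t] if drift is not None else 0.0)
    if sigma_loc > 0:
        x = x + rng.normal(0.0, sigma_loc, size=x.shape)
        y = y + rng.normal(0.0, sigma_loc, size=y.shape)
    df = pd.DataFrame(
        {"frame": t, "x": x, "y": y, "intensity": intensity, "track_id": fid, "channel": 0}
    ).sort_values(["frame", "track_id"], kind="stable")
    return LocalizationTable(df, pixel_size_nm=pixel_size_nm)


def simulate_filament_table(
    n_events: int,
    sigma_loc_px: float,
    mean_on_frames: float = 4.0,
    n_frames: int = 2000,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
    field_px: float = 32.0,
    n_lines: int = 5,
) -> LocalizationTable:
    """Localization table of a dense, static filament-grid structure.

    Binding/emission events occur at random positions along a grid of
    horizontal and vertical lines; each event stays on for a geometric
    number of consecutive frames (mean ``mean_on_frames``) and is
    re-localized each frame with i.i.d. per-axis noise ``sigma_loc_px``.
    Consecutive-frame re-detections of the same event make the table
    suitable for NeNA, and the static structure for FRC.
    """
    rng = np.random.default_rng(seed)
    line_pos = np.linspace(0.15 * field_px, 0.85 * field_px, n_lines)
    lo, hi = 0.05 * field_px, 0.95 * field_px
    frames, xs, ys = [], [], []
    for _ in range(n_events):
        u = rng.uniform(lo, hi)
        c = line_pos[rng.integers(0, n_lines)]
        if rng.random() < 0.5:
            sx, sy = u, c
        else:
            sx, sy = c, u
        duration = 1 + rng.geometric(1.0 / mean_on_frames)
        start = rng.integers(0, max(n_frames - duration, 1))
        for f in range(start, min(start + duration, n_frames)):
            frames.append(f)
            xs.append(sx + rng.normal(0, sigma_loc_px))
            ys.append(sy + rng.normal(0, sigma_loc_px))
    df = pd.DataFrame(
        {"frame": frames, "x": xs, "y": ys, "intensity": 1000.0}
    ).sort_values("frame", kind="stable")
    return LocalizationTable(df, pixel_size_nm=pixel_size_nm)


def make_smooth_drift(
    n_frames: int,
    amplitude_px: float,
    seed: int = 0,
    n_harmonics: int = 3,
) -> DriftTrace:
    """Smooth, slow lateral drift: a random sum of low-frequency sinusoids
    re-zeroed at frame 0 and scaled so the peak displacement magnitude equals
    ``amplitude_px``."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / max(n_frames - 1, 1)
    dx = np.zeros(n_frames)
    dy = np.zeros(n_frames)
    for k in range(1, n_harmonics + 1):
        ax, ay = rng.normal(size=2) / k
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        dx += ax * np.sin(np.pi * k * t + px)
        dy += ay * np.sin(np.pi * k * t + py)
    dx -= dx[0]
    dy -= dy[0]
    peak = np.max(np.hypot(dx, dy))
    if peak > 0:
        dx *= amplitude_px / peak
        dy *= amplitude_px / peak
    return DriftTrace(dx, dy, reference_frame=0)
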