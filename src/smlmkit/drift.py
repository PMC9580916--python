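"""Lateral drift estimation and correction.

Two estimators: fiducial-marker tracking (works for any sample that
contains stable bright markers; each marker's trajectory relative to its
own first observation is averaged across markers) and temporal image
cross-correlation (works only on structurally static samples; the movie
is split into time bins, each bin rendered, and the displacement of each
bin's rendering relative to the first bin read off the cross-correlation
peak, refined to sub-pixel by a parabola fit and interpolated to per-frame
resolution with a cubic spline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import warnings

from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .core_io import UNASSIGNED, DriftTrace, LocalizationTable
from .link import LinkParams, link_localizations
from .render import RenderParams, render_histogram

__all__ = [
    "FiducialParams",
    "CCParams",
    "estimate_drift_fiducial",
    "estimate_drift_cc",
    "apply_drift",
]


@dataclass(frozen=True)
class FiducialParams:
    """``min_presence_fraction``: fraction of movie frames a track must span
    to qualify as a fiducial; ``link_radius_px``: linking radius used when
    the table is not yet linked; ``smoothing_window_frames``: odd moving-
    average window for the averaged trace (1 = no smoothing)."""

    min_presence_fraction: float = 0.9
    link_radius_px: float = 1.0
    smoothing_window_frames: int = 1
    link_gap_frames: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_presence_fraction <= 1:
            raise ValueError("min_presence_fraction must be in (0, 1]")
        if self.smoothing_window_frames < 1 or self.smoothing_window_frames % 2 == 0:
            raise ValueError("smoothing_window_frames must be odd and >= 1")


@dataclass(frozen=True)
class CCParams:
    """``bin_frames``: temporal bin width in frames; ``zoom``: render
    sub-pixels per camera pixel; ``interp``: per-frame interpolation scheme
    ('spline' or 'linear'); ``smooth_sigma_render_px``: Gaussian kernel (in
    render pixels) applied to each bin's histogram before correlation —
    widens the correlation peak of sparse renders so the 3-point parabola
    refinement is unbiased (0 disables)."""

    bin_frames: int
    zoom: int = 5
    interp: str = "spline"
    smooth_sigma_render_px: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_frames < 1:
            raise ValueError("bin_frames must be >= 1")
        if self.zoom < 1:
            raise ValueError("zoom must be >= 1")
        if self.interp not in ("spline", "linear"):
            raise ValueError("interp must be 'spline' or 'linear'")


def estimate_drift_fiducial(
    table: LocalizationTable, params: FiducialParams, n_frames: int
) -> tuple[DriftTrace, list[int]]:
    """Drift trace from fiducial-marker tracks, plus the fiducial track ids.

    Tracks spanning at least ``min_presence_fraction * n_frames`` frames are
    taken as fiducials.  Each marker's displacement is measured relative to
    its own first observed position (avoiding bias when markers start on
    different frames); the per-frame average over markers is interpolated
    over missing frames, optionally smoothed, and finally re-zeroed at
    frame 0.
    """
    work = table
    if (work.df["track_id"] == UNASSIGNED).all():
        work = link_localizations(
            table.sorted_by_frame(),
            LinkParams(params.link_radius_px, params.link_gap_frames),
        )
    df = work.df
    spans = df.groupby("track_id")["frame"].agg(["min", "max"])
    span_len = spans["max"] - spans["min"] + 1
    fiducial_ids = span_len[span_len >= params.min_presence_fraction * n_frames].index.tolist()
    if not fiducial_ids:
        raise ValueError(
            "no track qualifies as a fiducial marker "
            f"(longest span {int(span_len.max()) if len(span_len) else 0} of {n_frames} frames; "
            f"required {params.min_presence_fraction * n_frames:.0f})"
        )

    acc_dx = np.zeros(n_frames)
    acc_dy = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    for tid in fiducial_ids:
        g = df[df["track_id"] == tid].sort_values("frame")
        t = g["frame"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        acc_dx[t] += x - x[0]
        acc_dy[t] += y - y[0]
        counts[t] += 1

    seen = counts > 0
    frames = np.arange(n_frames)
    dx = np.interp(frames, frames[seen], acc_dx[seen] / counts[seen])
    dy = np.interp(frames, frames[seen], acc_dy[seen] / counts[seen])

    w = params.smoothing_window_frames
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        dx = np.convolve(np.pad(dx, pad, mode="edge"), kernel, mode="valid")
        dy = np.convolve(np.pad(dy, pad, mode="edge"), kernel, mode="valid")

    dx -= dx[0]
    dy -= dy[0]
    return DriftTrace(dx, dy, reference_frame=0), [int(i) for i in fiducial_ids]


def _cc_peak_shift(ref_img: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """Sub-pixel displacement of ``img`` relative to ``ref_img`` from the
    spectral cross-correlation peak, refined by a 3-point parabola per axis.
    Returns (shift_cols, shift_rows) in (render-)pixel units."""
    f_ref = np.fft.fft2(ref_img)
    f_img = np.fft.fft2(img)
    cc = np.fft.ifft2(f_img * np.conj(f_ref)).real
    nr, nc = cc.shape
    pr, pc = np.unravel_index(np.argmax(cc), cc.shape)

    def parabola(values: np.ndarray, p: int, n: int) -> float:
        ym = values[(p - 1) % n]
        y0 = values[p]
        yp = values[(p + 1) % n]
        denom = ym - 2 * y0 + yp
        return 0.0 if denom == 0 else 0.5 * (ym - yp) / denom

    dr = pr + parabola(cc[:, pc], pr, nr)
    dc = pc + parabola(cc[pr, :], pc, nc)
    # wrap to signed shifts
    if dr > nr / 2:
        dr -= nr
    if dc > nc / 2:
        dc -= nc
    return dc, dr


def estimate_drift_cc(
    table: LocalizationTable, params: CCParams, n_frames: int
) -> DriftTrace:
    """Drift trace by temporal image cross-correlation.

    Requires a structurally static dataset.  Frames are partitioned into
    bins of ``bin_frames``; each bin is rendered as a 2D histogram at
    ``zoom``; the cross-correlation of every bin against bin 0 gives the
    bin's displacement, assigned to the bin's temporal center; the per-frame
    trace is interpolated with a cubic spline (flat beyond the outer bin
    centers).
    """
    n_bins = int(np.ceil(n_frames / params.bin_frames))
    if n_bins < 2:
        raise ValueError("need at least 2 temporal bins for cross-correlation drift estimation")

    df = table.df
    # common extent so all bin renders share a raster
    xmin = float(np.floor(df["x"].min())) - 1.0
    xmax = float(np.ceil(df["x"].max())) + 1.0
    ymin = float(np.floor(df["y"].min())) - 1.0
    ymax = float(np.ceil(df["y"].max())) + 1.0
    rp = RenderParams(zoom=params.zoom, method="histogram", extent=(xmin, xmax, ymin, ymax))

    centers = []
    shifts = []
    ref_img = None
    for b in range(n_bins):
        lo = b * params.bin_frames
        hi = min((b + 1) * params.bin_frames, n_frames)
        sub = df[(df["frame"] >= lo) & (df["frame"] < hi)]
        sub_table = replace(table, df=sub.reset_index(drop=True))
        img = render_histogram(sub_table, rp).data
        if params.smooth_sigma_render_px > 0:
            img = gaussian_filter(img, params.smooth_sigma_render_px)
        if b == 0:
            ref_img = img
            centers.append((lo + hi - 1) / 2.0)
            shifts.append((0.0, 0.0))
            continue
        sc, sr = _cc_peak_shift(ref_img, img)
        if abs(sc) > img.shape[1] * 0.4 or abs(sr) > img.shape[0] * 0.4:
            warnings.warn("cross-correlation peak near field border; shift may be unreliable",
                          stacklevel=2)
        centers.append((lo + hi - 1) / 2.0)
        shifts.append((sc / params.zoom, sr / params.zoom))

    centers = np.asarray(centers)
    sx = np.array([s[0] for s in shifts])
    sy = np.array([s[1] for s in shifts])
    frames = np.arange(n_frames, dtype=np.float64)
    if params.interp == "spline" and len(centers) >= 3:
        fx = CubicSpline(centers, sx)
        fy = CubicSpline(centers, sy)
        dx = fx(np.clip(frames, centers[0], centers[-1]))
        dy = fy(np.clip(frames, centers[0], centers[-1]))
    else:
        dx = np.interp(frames, centers, sx)
        dy = np.interp(frames, centers, sy)
    dx -= dx[0]
    dy -= dy[0]
    return DriftTrace(dx, dy, reference_frame=0)


def apply_drift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the drift trace from every localization position."""
    df = table.df
    if len(df) and int(df["frame"].max()) >= len(trace):
        raise ValueError("drift trace does not cover all frames present in the table")
    out = table.copy()
    f = out.df["frame"].to_numpy()
    out.df["x"] = out.df["x"].to_numpy() - trace.dx[f]
    out.df["y"] = out.df["y"].to_numpy() - trace.dy[f]
    return out
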