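"""Image resolution (Fourier ring correlation) and localization precision
(nearest-neighbour analysis, NeNA).

FRC: the localization list is split uniformly at random into two halves,
each rendered as a histogram on a common zero-padded square raster; the
ring-wise correlation of the two Fourier spectra is computed and the
structural resolution read off as the inverse of the spatial frequency
where the (smoothed) curve first drops through a threshold, typically
1/7 ~ 0.143.  A random split is used rather than odd/even frames: emitters
stay on across consecutive frames, so a frame-parity split correlates the
halves and overestimates resolution.

NeNA: most nearest-neighbour events in *adjacent frames* of non-merged
data are re-detections of the same emitter, so their true distance is
zero and the observed distances follow the noncentral-chi (Rayleigh) law
``p(d) = d/(2 sigma^2) * exp(-d^2/(4 sigma^2))`` whose sigma is the
per-axis localization precision.  NeNA fails only when the average on-time
is much below one frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core_io import LocalizationTable
from .render import RenderParams, render_histogram

__all__ = ["FrcCurve", "NenaFit", "frc_resolution", "nena_precision"]


@dataclass
class FrcCurve:
    """FRC value per spatial-frequency ring, the smoothed curve, and the
    resolution at the first threshold crossing (None when the curve never
    crosses within Nyquist)."""

    q: np.ndarray              # 1/nm per ring
    frc: np.ndarray
    smoothed: np.ndarray
    threshold: float
    resolution_nm: float | None
    render_pixel_nm: float
    seed: int


@dataclass
class NenaFit:
    """Fitted per-axis localization precision from next-frame
    nearest-neighbour distances."""

    sigma_px: float
    sigma_nm: float
    distances: np.ndarray      # px
    covariance: np.ndarray | None
    bin_width_px: float
    label: str = ""


def frc_resolution(
    table: LocalizationTable,
    render_pixel_nm: float,
    seed: int = 0,
    threshold: float = 1.0 / 7.0,
    smooth_span: int = 7,
    pad_factor: float = 1.25,
) -> FrcCurve:
    """Fourier ring correlation resolution of a localization dataset.

    ``render_pixel_nm`` sets the histogram raster (it should be of order
    half the localization precision); the two half-images share a square
    raster padded by ``pad_factor`` with zeros.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 localizations to split")
    rng = np.random.default_rng(seed)
    half_mask = rng.random(len(table)) < 0.5
    t1 = replace(table, df=table.df[half_mask].reset_index(drop=True))
    t2 = replace(table, df=table.df[~half_mask].reset_index(drop=True))
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("random split produced an empty half")

    zoom_equiv = table.pixel_size_nm / render_pixel_nm  # render bins per camera px
    df = table.df
    xmin, xmax = float(df["x"].min()), float(df["x"].max())
    ymin, ymax = float(df["y"].min()), float(df["y"].max())
    side_px = max(xmax - xmin, ymax - ymin) * pad_factor + 2.0 / zoom_equiv
    n_side = int(np.ceil(side_px * zoom_equiv))
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    half_side = n_side / zoom_equiv / 2.0
    extent = (cx - half_side, cx + half_side, cy - half_side, cy + half_side)
    # integer zoom is not required here: bin positions in nm
    img1 = _render_nm(t1, extent, n_side)
    img2 = _render_nm(t2, extent, n_side)

    f1 = np.fft.fft2(img1)
    f2 = np.fft.fft2(img2)
    fx = np.fft.fftfreq(n_side) * n_side
    ring = np.rint(np.hypot(*np.meshgrid(fx, fx, indexing="ij"))).astype(np.int64)
    n_rings = n_side // 2 + 1
    sel = ring < n_rings
    num = np.bincount(ring[sel], weights=(f1 * np.conj(f2)).real[sel], minlength=n_rings)
    den1 = np.bincount(ring[sel], weights=np.abs(f1[sel]) ** 2, minlength=n_rings)
    den2 = np.bincount(ring[sel], weights=np.abs(f2[sel]) ** 2, minlength=n_rings)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(den1 * den2)
    frc = np.nan_to_num(frc, nan=0.0)

    # centered moving average with edge-shrinking window
    span = max(int(smooth_span), 1)
    hw = span // 2
    smoothed = np.array([
        frc[max(i - hw, 0): i + hw + 1].mean() for i in range(n_rings)
    ])

    q = np.arange(n_rings) / (n_side * render_pixel_nm)
    resolution = None
    for i in range(1, n_rings):
        if smoothed[i] < threshold <= smoothed[i - 1]:
            frac = (smoothed[i - 1] - threshold) / (smoothed[i - 1] - smoothed[i])
            q_star = q[i - 1] + frac * (q[i] - q[i - 1])
            if q_star > 0:
                resolution = 1.0 / q_star
            break
    return FrcCurve(q, frc, smoothed, threshold, resolution, render_pixel_nm, seed)


def _render_nm(table: LocalizationTable, extent, n_side: int) -> np.ndarray:
    """Square histogram raster with exactly n_side bins per axis."""
    xmin, xmax, ymin, ymax = extent
    df = table.df
    img, _, _ = np.histogram2d(
        df["y"].to_numpy(), df["x"].to_numpy(),
        bins=n_side, range=[[ymin, ymax], [xmin, xmax]],
    )
    return img


def nena_precision(
    table: LocalizationTable,
    intensity_split: float | None = None,
    capture_radius_px: float = 2.0,
    n_bins: int = 50,
) -> NenaFit | list[NenaFit]:
    """NeNA localization precision from next-frame nearest neighbours.

    For every localization in frame t the distance to its nearest neighbour
    in frame t+1 (within ``capture_radius_px``) is collected; the histogram
    is fitted with the Rayleigh law whose scale is ``sqrt(2) * sigma``.
    With ``intensity_split`` given, the table is partitioned at that
    intensity (e.g. bright fiducials vs dim emitters) and fitted separately,
    returning ``[below, above]``.
    """
    if intensity_split is not None:
        below = replace(table, df=table.df[table.df["intensity"] < intensity_split].reset_index(drop=True))
        above = replace(table, df=table.df[table.df["intensity"] >= intensity_split].reset_index(drop=True))
        fit_lo = nena_precision(below, None, capture_radius_px, n_bins)
        fit_hi = nena_precision(above, None, capture_radius_px, n_bins)
        fit_lo.label = f"intensity < {intensity_split:g}"
        fit_hi.label = f"intensity >= {intensity_split:g}"
        return [fit_lo, fit_hi]

    df = table.df
    dists = []
    frames = np.sort(df["frame"].unique())
    by_frame = {int(f): g[["x", "y"]].to_numpy() for f, g in df.groupby("frame")}
    for f in frames:
        nxt = by_frame.get(int(f) + 1)
        if nxt is None or len(nxt) == 0:
            continue
        tree = cKDTree(nxt)
        d, _ = tree.query(by_frame[int(f)], distance_upper_bound=capture_radius_px)
        dists.append(d[np.isfinite(d)])
    d = np.concatenate(dists) if dists else np.empty(0)
    if len(d) < 10:
        raise ValueError(f"too few next-frame neighbour distances ({len(d)})")
    if len(d) < 100:
        warnings.warn("fewer than 100 distances; NeNA fit may be unreliable", stacklevel=2)
    if np.max(d) <= 0:
        raise ValueError("all nearest-neighbour distances are zero; degenerate fit")

    counts, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma0 = max(np.median(d) / 1.6651, 1e-9)  # Rayleigh median = sigma*sqrt(2)*sqrt(ln 4)

    def residual(theta):
        s2 = np.exp(theta[0]) ** 2
        return centers / (2 * s2) * np.exp(-(centers**2) / (4 * s2)) - counts

    sol = least_squares(residual, [np.log(sigma0)], max_nfev=10000)
    if not np.isfinite(sol.cost):
        raise RuntimeError("NeNA fit did not converge")
    sigma = float(np.exp(sol.x[0]))
    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * 2 * sol.cost / max(len(counts) - 1, 1)
    except np.linalg.LinAlgError:
        pass
    return NenaFit(
        sigma_px=sigma,
        sigma_nm=sigma * table.pixel_size_nm,
        distances=d,
        covariance=cov,
        bin_width_px=float(edges[1] - edges[0]),
    )
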