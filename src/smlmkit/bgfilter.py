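"""Temporal median background subtraction.

For every pixel at frame t, the median over a sliding window of ``i``
frames centered on t is subtracted.  The blinking equilibrium of SMLM
fluorophores favours the off state, so the temporal median tracks the
(slowly varying, spatially inhomogeneous) background rather than the
signal.  Near the movie edges the window is shifted — never shrunk — so
it always contains exactly ``i`` frames anchored at the movie start/end,
keeping the statistic's breakdown point constant.

The window must be substantially longer than the longest on-period of a
single emitter (at least twice; ~50 frames is typical, hence the default
of 51).  This filter must not be used when emitters are on more than half
the time: the median would then track signal, not background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import Movie

__all__ = ["MedianFilterParams", "temporal_median_filter"]


@dataclass(frozen=True)
class MedianFilterParams:
    """``window_frames`` is the odd temporal window length ``i``."""

    window_frames: int = 51

    def validate(self, n_frames: int) -> None:
        i = self.window_frames
        if i % 2 == 0:
            raise ValueError(f"window_frames must be odd; got {i}")
        if i < 3:
            raise ValueError(f"window_frames must be >= 3; got {i}")
        if i > n_frames:
            raise ValueError(f"window_frames ({i}) exceeds movie length ({n_frames})")


def temporal_median_filter(
    movie: Movie, params: MedianFilterParams = MedianFilterParams(), clamp: bool = True
) -> Movie:
    """Subtract the per-pixel sliding temporal median from a movie.

    Parameters
    ----------
    movie
        Input movie.
    params
        Window length configuration.
    clamp
        Clamp negative differences at 0 (default).  Disable to keep signed
        output, e.g. when feeding the result into difference-of-Gaussian
        detection that tolerates negatives.
    """
    params.validate(movie.n_frames)
    i = params.window_frames
    half = (i - 1) // 2
    data = movie.data.astype(np.float64)
    n = movie.n_frames

    # Medians of all n - i + 1 distinct windows along the time axis.
    windows = sliding_window_view(data, i, axis=0)  # (n-i+1, rows, cols, i)
    medians = np.median(windows, axis=-1)

    # Frame t uses the window starting at clip(t - half, 0, n - i):
    # shifted (not shrunk) at both movie edges.
    starts = np.clip(np.arange(n) - half, 0, n - i)
    out = data - medians[starts]
    if clamp:
        np.clip(out, 0.0, None, out=out)
    return Movie(out, pixel_size_nm=movie.pixel_size_nm, frame_interval_s=movie.frame_interval_s)
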