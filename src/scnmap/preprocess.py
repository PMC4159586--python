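"""Stack cleaning, superpixel coarsening, masking and trace extraction.

The raw recordings are contaminated by cosmic-ray hits (isolated
single-voxel spikes) and carry a dim extra-tissue background.  The
cleaning chain is: despike by quantile -> average 2x2 tiles into
superpixels -> mask the extra-tissue area.  The module also extracts
3x3-pixel cell-ROI traces, detects peaks/troughs over a moving 15-h
window, and produces trough-anchored normalized frames for display.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ImageStack, SeriesMatrix


def despike(stack: ImageStack, quantile: float = 0.0001) -> ImageStack:
    """Replace extreme voxels by their spatiotemporal neighborhood mean.

    Every voxel at or beyond the upper ``1 - quantile`` or lower
    ``quantile`` quantile of all voxel values in the stack is replaced by
    the mean of its 3x3x3 neighborhood (previous, same and next frame)
    excluding the voxel itself, truncated at the stack borders.  Ties at
    the thresholds are all replaced.  Quantiles are computed once on the
    raw stack, so the operation is a single pass.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    if stack.n_frames < 3:
        raise ValueError("despiking needs at least 3 frames for the "
                         "temporal neighborhood")
    data = stack.data
    lo = np.quantile(data, quantile)
    hi = np.quantile(data, 1.0 - quantile)
    extreme = (data <= lo) | (data >= hi)
    if hi == lo:
        # Degenerate histogram (e.g. constant stack): every voxel ties both
        # thresholds; the replacement mean equals the value, so skip.
        return ImageStack(data.copy(), stack.dt_hours, stack.pixel_size_um)

    kernel = np.ones((3, 3, 3))
    box_sum = ndimage.correlate(data, kernel, mode="constant", cval=0.0)
    box_count = ndimage.correlate(
        np.ones_like(data), kernel, mode="constant", cval=0.0
    )
    neigh_mean = (box_sum - data) / (box_count - 1.0)

    out = data.copy()
    out[extreme] = neigh_mean[extreme]
    return ImageStack(out, stack.dt_hours, stack.pixel_size_um)


def coarsen(stack: ImageStack, factor: int = 2) -> SeriesMatrix:
    """Average ``factor x factor`` pixel tiles into superpixel time series.

    A 256x256 frame at the default factor yields 128x128 superpixels.
    Frame dimensions must be divisible by ``factor``; no implicit padding
    is performed.  Total brightness is conserved: the sum of superpixel
    values times ``factor**2`` equals the pixel sum in every frame.
    """
    T, H, W = stack.shape
    if H % factor or W % factor:
        raise ValueError(
            f"frame size {H}x{W} not divisible by factor {factor}"
        )
    h, w = H // factor, W // factor
    coarse = stack.data.reshape(T, h, factor, w, factor).mean(axis=(2, 4))
    series = coarse.reshape(T, h * w).T
    rows, cols = np.divmod(np.arange(h * w), w)
    return SeriesMatrix(
        series,
        np.column_stack([rows, cols]),
        np.ones(h * w, dtype=bool),
        dt_hours=stack.dt_hours,
        superpixel_size_px=factor,
        grid_shape=(h, w),
    )


def auto_mask(stack: ImageStack, factor: int = 2,
              user_mask: np.ndarray | None = None,
              min_object_size: int = 8) -> np.ndarray:
    """Tissue mask at superpixel resolution.

    By default the mask is True where the time-mean superpixel brightness
    exceeds an Otsu threshold of the time-mean image, followed by a 3x3
    binary opening and removal of connected components smaller than
    ``min_object_size`` superpixels: tissue is a contiguous blob, so
    bright specks and one-superpixel protrusions (noise, despiked
    cosmic-ray remnants at the tissue border) are artifacts.  A
    user-supplied pixel-resolution mask overrides the automatic choice
    and is downsampled by logical OR over each tile, with no cleanup
    applied.
    """
    T, H, W = stack.shape
    if H % factor or W % factor:
        raise ValueError("frame size not divisible by factor")
    h, w = H // factor, W // factor
    if user_mask is not None:
        user_mask = np.asarray(user_mask, dtype=bool)
        if user_mask.shape != (H, W):
            raise ValueError("user mask must match the frame shape")
        return user_mask.reshape(h, factor, w, factor).any(axis=(1, 3))

    mean_img = stack.data.mean(axis=0)
    coarse_mean = mean_img.reshape(h, factor, w, factor).mean(axis=(1, 3))
    if np.allclose(coarse_mean, coarse_mean.flat[0]):
        raise ValueError(
            "time-mean image is uniform; automatic masking is impossible — "
            "supply a tissue mask explicitly"
        )
    threshold = threshold_otsu(coarse_mean)
    mask = coarse_mean > threshold
    mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
    if min_object_size > 1:
        comp, n_comp = ndimage.label(mask)
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= min_object_size)
        mask = np.isin(comp, keep[keep > 0])
    if not mask.any():
        raise ValueError("automatic mask is empty; supply a tissue mask")
    return mask


def apply_mask(series: SeriesMatrix, mask: np.ndarray) -> SeriesMatrix:
    """Set the in_mask flags of a grid SeriesMatrix from a mask image."""
    if series.grid_shape is None or mask.shape != series.grid_shape:
        raise ValueError("mask shape must equal the superpixel grid shape")
    flags = mask[series.coords[:, 0], series.coords[:, 1]]
    return SeriesMatrix(
        series.series, series.coords, flags,
        dt_hours=series.dt_hours,
        superpixel_size_px=series.superpixel_size_px,
        grid_shape=series.grid_shape,
    )


def _window_extrema(X: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean peak/trough masks for each row of X (vectorized).

    An index is a peak (trough) iff it attains the maximum (minimum) of
    the centered window of ``2*half + 1`` samples and no earlier index in
    the window attains the same value (plateaus take the earliest index);
    windows where max == min (locally constant) yield nothing, and the
    first/last ``half`` indices are excluded as edge artifacts.
    """
    n = X.shape[1]
    size = 2 * half + 1
    wmax = ndimage.maximum_filter1d(X, size=size, axis=1, mode="nearest")
    wmin = ndimage.minimum_filter1d(X, size=size, axis=1, mode="nearest")
    # running extrema of the window's earlier part [i - half, i - 1]:
    # a centered length-half filter, shifted right so it ends at i - 1
    shift = 1 + (half - 1) // 2
    mx = ndimage.maximum_filter1d(X, size=half, axis=1, mode="constant",
                                  cval=-np.inf)
    mn = ndimage.minimum_filter1d(X, size=half, axis=1, mode="constant",
                                  cval=np.inf)
    prevmax = np.full_like(X, -np.inf)
    prevmin = np.full_like(X, np.inf)
    prevmax[:, shift:] = mx[:, :n - shift]
    prevmin[:, shift:] = mn[:, :n - shift]
    varying = wmax > wmin
    peaks = (X >= wmax) & (X > prevmax) & varying
    troughs = (X <= wmin) & (X < prevmin) & varying
    peaks[:, :half] = peaks[:, n - half:] = False
    troughs[:, :half] = troughs[:, n - half:] = False
    return peaks, troughs


def _half_window(n: int, dt_hours: float, window_hours: float) -> int:
    if n * dt_hours <= window_hours:
        raise ValueError("series shorter than the extremum window")
    return max(1, int(round(window_hours / (2.0 * dt_hours))))


def peaks_troughs(series: np.ndarray, dt_hours: float,
                  window_hours: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Local extrema of one series over a moving centered window.

    An index is a peak (trough) iff it is the maximum (minimum) of the
    centered window of width ``window_hours``, taking the earliest index
    on plateaus.  Indices within half a window of either end are excluded
    to avoid edge artifacts; a constant series yields no extrema.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    half = _half_window(series.shape[1], dt_hours, window_hours)
    peaks, troughs = _window_extrema(series, half)
    return np.flatnonzero(peaks[0]), np.flatnonzero(troughs[0])


def batch_peaks(series_2d: np.ndarray, dt_hours: float,
                window_hours: float = 15.0) -> np.ndarray:
    """Boolean peak mask (n_series x T) under the peaks_troughs rule."""
    X = np.atleast_2d(np.asarray(series_2d, dtype=float))
    half = _half_window(X.shape[1], dt_hours, window_hours)
    peaks, _ = _window_extrema(X, half)
    return peaks


def normalize_frames(
    stack: ImageStack,
    interval_hours: float = 6.0,
    mask: np.ndarray | None = None,
    window_hours: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trough-anchored, jointly normalized display frames.

    Frames are selected every ``interval_hours`` starting at the first
    trough of the frame-mean series ("time zero").  The selected frames
    are rescaled jointly: the global maximum maps to 1 and the median
    extra-mask (background) value maps to 0, then clipped to [0, 1].

    Returns ``(times_hours, frames)`` with times measured from the start
    of the recording.
    """
    mean_series = stack.frame_mean_series()
    _, troughs = peaks_troughs(mean_series, stack.dt_hours, window_hours)
    if troughs.size == 0:
        raise ValueError("no trough found on the frame-mean series")
    t0 = int(troughs[0])
    step = max(1, int(round(interval_hours / stack.dt_hours)))
    idx = np.arange(t0, stack.n_frames, step)
    selected = stack.data[idx]

    T, H, W = stack.shape
    if mask is None:
        mean_img = stack.data.mean(axis=0)
        pix_mask = mean_img > threshold_otsu(mean_img)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape == (H, W):
            pix_mask = mask
        else:
            # superpixel mask: upsample
            fh, fw = H // mask.shape[0], W // mask.shape[1]
            pix_mask = np.kron(mask, np.ones((fh, fw), dtype=bool))
    background = np.median(selected[:, ~pix_mask]) if (~pix_mask).any() else 0.0
    top = selected.max()
    if top <= background:
        raise ValueError("degenerate brightness range for normalization")
    frames = np.clip((selected - background) / (top - background), 0.0, 1.0)
    return idx * stack.dt_hours, frames


def extract_roi_series(stack: ImageStack, centers) -> SeriesMatrix:
    """Mean time series over 3x3 pixel squares at given cell centers.

    Centers within one pixel of the border cannot host a full 3x3 square;
    they are skipped with a warning.
    """
    T, H, W = stack.shape
    kept_series, kept_centers = [], []
    for (r, c) in centers:
        r, c = int(r), int(c)
        if not (1 <= r < H - 1 and 1 <= c < W - 1):
            warnings.warn(
                f"ROI center ({r}, {c}) is within 1 px of the border; skipped"
            )
            continue
        patch = stack.data[:, r - 1:r + 2, c - 1:c + 2]
        kept_series.append(patch.mean(axis=(1, 2)))
        kept_centers.append((r, c))
    if not kept_series:
        raise ValueError("no valid ROI centers")
    return SeriesMatrix(
        np.asarray(kept_series),
        np.asarray(kept_centers),
        np.ones(len(kept_series), dtype=bool),
        dt_hours=stack.dt_hours,
        superpixel_size_px=3,
    )
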