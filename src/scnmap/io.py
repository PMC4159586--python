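"""Containers and file I/O for bioluminescence image stacks.

A recording is a multi-frame grayscale TIFF (one frame per time point,
uniform sampling) accompanied by a JSON sidecar holding the sampling
interval in hours and the pixel size in micrometres.  Superpixel time
series are exchanged as plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A T x H x W stack of nonnegative brightness values.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Brightness per frame; finite and >= 0.
    dt_hours : float
        Sampling interval between frames, in hours.
    pixel_size_um : float
        Side length of one camera pixel in micrometres (5 for the
        recordings this pipeline was designed around).
    """

    data: np.ndarray
    dt_hours: float = 0.5
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be T x H x W")
        if self.data.shape[0] < 2:
            raise ValueError("stack must contain at least 2 frames")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("brightness values must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times_hours(self) -> np.ndarray:
        """Frame acquisition times, starting at 0 h."""
        return np.arange(self.n_frames) * self.dt_hours

    def frame_mean_series(self) -> np.ndarray:
        """Mean brightness of the full frame at each time point."""
        return self.data.mean(axis=(1, 2))


@dataclass
class SeriesMatrix:
    """Time series of superpixels (or cell ROIs) on a grid.

    ``series`` holds one row per superpixel; ``coords`` the (row, col)
    grid position of each; ``in_mask`` flags superpixels inside the
    tissue mask.  Rows are ordered row-major over the grid when the
    matrix comes from :func:`scnmap.preprocess.coarsen`.
    """

    series: np.ndarray
    coords: np.ndarray
    in_mask: np.ndarray
    dt_hours: float = 0.5
    superpixel_size_px: int = 2
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        self.coords = np.asarray(self.coords)
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        if self.coords.shape != (self.series.shape[0], 2):
            raise ValueError("coords must be n x 2")
        if self.in_mask.shape != (self.series.shape[0],):
            raise ValueError("in_mask must have one flag per series")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series must be finite")

    @property
    def n_series(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]

    def masked(self) -> "SeriesMatrix":
        """Restrict to in-mask rows."""
        keep = self.in_mask
        return SeriesMatrix(
            self.series[keep],
            self.coords[keep],
            np.ones(int(keep.sum()), dtype=bool),
            dt_hours=self.dt_hours,
            superpixel_size_px=self.superpixel_size_px,
            grid_shape=self.grid_shape,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "superpixel_id": np.arange(self.n_series),
            "row": self.coords[:, 0],
            "col": self.coords[:, 1],
            "in_mask": self.in_mask.astype(int),
        }
        df = pd.DataFrame(cols)
        frames = pd.DataFrame(
            self.series, columns=[f"t{j}" for j in range(self.n_frames)]
        )
        return pd.concat([df, frames], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, dt_hours: float = 0.5,
                 superpixel_size_px: int = 2) -> "SeriesMatrix":
        df = pd.read_csv(path)
        tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
        tcols.sort(key=lambda c: int(c[1:]))
        return cls(
            df[tcols].to_numpy(float),
            df[["row", "col"]].to_numpy(),
            df["in_mask"].to_numpy(bool),
            dt_hours=dt_hours,
            superpixel_size_px=superpixel_size_px,
        )


def write_stack(path: str | Path, stack: ImageStack, **sidecar_extra) -> None:
    """Write a stack as 16-bit multi-frame TIFF plus a JSON sidecar.

    Values are clipped to the uint16 range; the sidecar records
    ``dt_hours`` and ``pixel_size_um`` plus any extra keys supplied.
    """
    path = Path(path)
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {"dt_hours": stack.dt_hours, "pixel_size_um": stack.pixel_size_um}
    meta.update(sidecar_extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-frame TIFF and its JSON sidecar."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageStack(
        data,
        dt_hours=float(meta.get("dt_hours", 0.5)),
        pixel_size_um=float(meta.get("pixel_size_um", 5.0)),
    )


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label image (0 = background/excluded) as TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.int32))
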