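"""Ground-truthed synthetic SCN bioluminescence movies.

The simulator plants spatially contiguous oscillator regions on a dim
background and renders each pixel as a damped raised cosine mixture plus
Gaussian noise and isolated cosmic-ray spikes:

    I(t, r, c) = background                                  (outside tissue)
    I(t, r, c) = baseline + sum_j A_j * exp(-gamma * t) *
                 (1 + cos(2*pi*(t - phi_j) / P_j)) / 2 + noise   (in region)

with t in hours.  The raised cosine keeps brightness nonnegative and the
multiplicative exponential reproduces the damped low-amplitude phenotype
of coupling-deficient tissue.

Four presets emulate the phenotypes this pipeline is meant to separate:

``wt``
    Five contiguous regions sharing a 24-h rhythm at equispaced phases
    covering the full cycle, plus region-specific ultradian components:
    both spatial and temporal organisation.
``cry_null``
    No circadian component at all; regions carry distinct ultradian
    components on distinct baselines: spatial order without a 24-h rhythm.
``vpac2_organised``
    Contiguous phase regions with a weak, strongly damped circadian
    rhythm: both organisations present but fragile.
``vpac2_disorganised``
    Every 2x2 pixel block gets an independent random circadian phase:
    temporal (rhythmic) content without contiguous spatial organisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack

PRESET_NAMES = ("wt", "cry_null", "vpac2_organised", "vpac2_disorganised")


@dataclass
class Region:
    """One contiguous oscillator patch.

    components is a list of (period_hours, amplitude, phase_hours)
    tuples; damping_rate is the per-hour exponential decay applied to
    every component amplitude.
    """

    pixel_set: frozenset
    baseline: float = 0.0
    components: list = field(default_factory=list)
    damping_rate: float = 0.0

    def series(self, times_hours: np.ndarray) -> np.ndarray:
        """Noise-free brightness of this region over time."""
        out = np.full(times_hours.shape, float(self.baseline))
        damp = np.exp(-self.damping_rate * times_hours)
        for period, amplitude, phase in self.components:
            out += (
                amplitude
                * damp
                * (1.0 + np.cos(2.0 * np.pi * (times_hours - phase) / period))
                / 2.0
            )
        return out


@dataclass
class PhenotypeConfig:
    """Full description of one synthetic movie."""

    frame_count: int
    dt_hours: float
    height: int
    width: int
    regions: list
    background_level: float = 10.0
    noise_sd: float = 0.0
    spike_fraction: float = 0.0
    spike_magnitude: float = 5.0
    rng_seed: int = 0
    pixel_size_um: float = 5.0
    name: str = "custom"

    def validate(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        if not 0 <= self.spike_fraction <= 0.01:
            raise ValueError("spike_fraction must lie in [0, 0.01]")
        seen: set = set()
        for region in self.regions:
            for period, amplitude, _ in region.components:
                if period <= 2 * self.dt_hours:
                    raise ValueError(
                        f"component period {period} h is not resolvable at "
                        f"dt = {self.dt_hours} h (need period > 2*dt)"
                    )
                if amplitude < 0:
                    raise ValueError("component amplitudes must be >= 0")
            for (r, c) in region.pixel_set:
                if not (0 <= r < self.height and 0 <= c < self.width):
                    raise ValueError("region pixel outside the frame")
                if (r, c) in seen:
                    raise ValueError("regions overlap")
                seen.add((r, c))


@dataclass
class GroundTruth:
    """What the generator planted: labels, phases, and spike positions."""

    label_image: np.ndarray
    phase_map: dict
    spike_coordinates: list

    def phase_frame(self) -> pd.DataFrame:
        ids = sorted(self.phase_map)
        return pd.DataFrame(
            {"region_id": ids, "phase_hours": [self.phase_map[i] for i in ids]}
        )


def _circadian_phase(region: Region) -> float | None:
    """Phase of the region's circadian (18-30 h) component, if any."""
    for period, amplitude, phase in region.components:
        if 18.0 <= period <= 30.0 and amplitude > 0:
            return float(phase)
    return None


def generate_movie(config: PhenotypeConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a config into a stack plus its ground truth.

    Deterministic given ``config.rng_seed``: the same config produces a
    bit-identical stack.  Noise is additive Gaussian clipped at zero;
    spikes replace single voxels with ``spike_magnitude`` times the
    noise-free maximum of the movie.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    T, H, W = config.frame_count, config.height, config.width
    times = np.arange(T) * config.dt_hours

    clean = np.full((T, H, W), float(config.background_level))
    label_image = np.zeros((H, W), dtype=np.int32)
    phase_map: dict = {}
    for rid, region in enumerate(config.regions, start=1):
        series = region.series(times)
        idx = np.array(sorted(region.pixel_set))
        clean[:, idx[:, 0], idx[:, 1]] = series[:, None]
        label_image[idx[:, 0], idx[:, 1]] = rid
        phase = _circadian_phase(region)
        if phase is not None:
            phase_map[rid] = phase

    data = clean
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=(T, H, W))
        np.clip(data, 0.0, None, out=data)

    spike_coordinates: list = []
    if config.spike_fraction > 0:
        n_spikes = int(round(config.spike_fraction * T * H * W))
        if n_spikes:
            flat = rng.choice(T * H * W, size=n_spikes, replace=False)
            coords = np.unravel_index(flat, (T, H, W))
            data[coords] = config.spike_magnitude * clean.max()
            spike_coordinates = list(zip(*(c.tolist() for c in coords)))

    stack = ImageStack(data, dt_hours=config.dt_hours,
                       pixel_size_um=config.pixel_size_um)
    return stack, GroundTruth(label_image, phase_map, spike_coordinates)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _strip_regions(height: int, width: int, margin: int = 24) -> list[frozenset]:
    """Five compact contiguous blocks tiling a central square.

    Three blocks across the top half, two across the bottom half, with
    all block edges aligned to the 2x2 superpixel grid so that region
    boundaries are exact at superpixel resolution.
    """
    top, bottom = margin, height - margin
    left, right = margin, width - margin
    # split so the three top and two bottom blocks have near-equal areas
    mid = top + round((bottom - top) * 0.6)
    mid -= mid % 2
    span = right - left

    def block(r0, r1, c0, c1):
        return frozenset((r, c) for r in range(r0, r1) for c in range(c0, c1))

    w3 = span // 3 - (span // 3) % 2
    w2 = span // 2 - (span // 2) % 2
    return [
        block(top, mid, left, left + w3),
        block(top, mid, left + w3, left + 2 * w3),
        block(top, mid, left + 2 * w3, right),
        block(mid, bottom, left, left + w2),
        block(mid, bottom, left + w2, right),
    ]


def preset(name: str, frame_count: int = 240, dt_hours: float = 0.5,
           height: int = 128, width: int = 128, seed: int = 0) -> PhenotypeConfig:
    """Build a phenotype preset.

    Sizes default to 128 x 128 pixel frames (64 x 64 superpixels) over
    120 h of recording at a 30-min sampling interval.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    strips = _strip_regions(height, width)
    wt_phases = [0.0, 4.8, 9.6, 14.4, 19.2]
    regions: list[Region]

    if name == "wt":
        ultradian_periods = [8.0, 10.0, 12.0, 14.0, 16.0]
        regions = [
            Region(
                pixel_set=strips[i],
                baseline=30.0,
                components=[
                    (24.0, 100.0, wt_phases[i]),
                    (ultradian_periods[i], 15.0, 1.3 * i),
                ],
                damping_rate=0.005,
            )
            for i in range(5)
        ]
        noise_sd = 5.0
    elif name == "cry_null":
        ultradian_periods = [4.0, 6.0, 8.0, 12.0, 16.0]
        baselines = [60.0, 75.0, 90.0, 105.0, 120.0]
        regions = [
            Region(
                pixel_set=strips[i],
                baseline=baselines[i],
                components=[(ultradian_periods[i], 60.0, 0.9 * i)],
                damping_rate=0.002,
            )
            for i in range(5)
        ]
        noise_sd = 5.0
    elif name == "vpac2_organised":
        ultradian_periods = [8.0, 10.0, 12.0, 14.0, 16.0]
        regions = [
            Region(
                pixel_set=strips[i],
                baseline=30.0,
                components=[
                    (24.0, 45.0, wt_phases[i]),
                    (ultradian_periods[i], 8.0, 1.3 * i),
                ],
                damping_rate=0.03,
            )
            for i in range(5)
        ]
        noise_sd = 4.5
    else:  # vpac2_disorganised: one region per 2x2 block, random phase
        rng = np.random.default_rng(seed + 104729)
        regions = []
        tissue = set().union(*strips)
        blocks = sorted({(r - r % 2, c - c % 2) for (r, c) in tissue})
        phases = rng.uniform(0.0, 24.0, size=len(blocks))
        for (r0, c0), phi in zip(blocks, phases):
            block = frozenset(
                (r0 + dr, c0 + dc) for dr in (0, 1) for dc in (0, 1)
            ) & tissue
            regions.append(Region(
                pixel_set=block,
                baseline=30.0,
                components=[(24.0, 40.0, float(phi))],
                damping_rate=0.02,
            ))
        noise_sd = 12.0

    return PhenotypeConfig(
        frame_count=frame_count,
        dt_hours=dt_hours,
        height=height,
        width=width,
        regions=regions,
        background_level=10.0,
        noise_sd=noise_sd,
        spike_fraction=1e-4,
        spike_magnitude=5.0,
        rng_seed=seed,
        name=name,
    )
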