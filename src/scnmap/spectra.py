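"""Fourier amplitude spectra, white-noise significance lines, notch filter.

Rhythmicity of a cluster is judged against the null hypothesis of
uniform Fourier coefficients (white noise): the amplitude spectrum is
compared with lines at 2 SDs either side of its own across-bin mean.  A
band is significant when its amplitude exceeds the upper line.  Periods
are classed as ultradian (< 18 h), circadian (18-30 h inclusive) or
infradian (> 30 h).  The band-stop (notch) filter deletes the 18-30 h
coefficients and inverse-transforms, leaving only non-circadian content
for re-clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

CIRCADIAN_BAND_HOURS = (18.0, 30.0)

__all__ = [
    "power_spectrum",
    "noise_lines",
    "notch_filter",
    "band_classification",
    "circadian_significant",
    "SpectrumSet",
    "cluster_spectra",
    "NotchFilter",
    "CIRCADIAN_BAND_HOURS",
]


def power_spectrum(series: np.ndarray,
                   dt_hours: float) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Fourier amplitude spectrum over positive frequencies.

    The series mean (DC) is removed before transforming; no taper or
    detrend is applied.  Returns ``(periods_hours, amplitude)`` with
    amplitude = |X_f| of the positive-frequency coefficients.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    if dt_hours <= 0:
        raise ValueError("dt_hours must be positive")
    coeffs = np.fft.rfft(series - series.mean())
    freqs = np.fft.rfftfreq(n, d=dt_hours)
    amplitude = np.abs(coeffs[1:])
    periods = 1.0 / freqs[1:]
    return periods, amplitude


def noise_lines(amplitude: np.ndarray) -> tuple[float, float, float]:
    """White-noise significance lines for an amplitude spectrum.

    Under uniform Fourier coefficients the expected amplitude is flat
    across bins, so the null is summarised by the across-bin mean and SD
    of the observed spectrum.  Returns (mean, mean + 2 SD, mean - 2 SD).
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.size == 0:
        raise ValueError("empty spectrum")
    if amplitude.size < 8:
        warnings.warn("fewer than 8 bins: noise-line SD is unstable")
    mean = float(amplitude.mean())
    sd = float(amplitude.std(ddof=0))
    return mean, mean + 2.0 * sd, mean - 2.0 * sd


def band_classification(periods_hours: np.ndarray,
                        band_hours=CIRCADIAN_BAND_HOURS) -> np.ndarray:
    """'ultradian' / 'circadian' / 'infradian' flag per period bin."""
    periods = np.asarray(periods_hours, dtype=float)
    lo, hi = band_hours
    flags = np.where(periods < lo, "ultradian",
                     np.where(periods > hi, "infradian", "circadian"))
    return flags.astype(object)


def circadian_significant(periods_hours: np.ndarray, amplitude: np.ndarray,
                          band_hours=CIRCADIAN_BAND_HOURS) -> bool:
    """Does any circadian-band bin exceed the upper noise line?"""
    _, upper, _ = noise_lines(amplitude)
    lo, hi = band_hours
    in_band = (periods_hours >= lo) & (periods_hours <= hi)
    return bool(in_band.any() and amplitude[in_band].max() > upper)


def notch_filter(series: np.ndarray, dt_hours: float,
                 band_hours=CIRCADIAN_BAND_HOURS) -> np.ndarray:
    """Band-stop filter deleting all Fourier bins with period in the band.

    Coefficients whose period lies in ``band_hours`` (inclusive) are set
    to zero (conjugates handled by the real transform) and the inverse
    transform is returned, so the filtered spectrum is exactly flat at
    circadian frequencies.  Exactly idempotent and linear.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    lo, hi = band_hours
    freqs = np.fft.rfftfreq(n, d=dt_hours)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.where(freqs > 0, freqs, 1.0),
                           np.inf)
    stop = (periods >= lo) & (periods <= hi)
    if not stop.any():
        warnings.warn(
            f"no Fourier bin falls in the {lo}-{hi} h band; series returned "
            "unchanged"
        )
        return series.copy()
    coeffs = np.fft.rfft(series)
    coeffs[stop] = 0.0
    return np.fft.irfft(coeffs, n=n)


class NotchFilter(TransformerMixin, BaseEstimator):
    """Row-wise band-stop transformer for series matrices.

    Parameters
    ----------
    dt_hours : float
        Sampling interval of the columns.
    band_hours : tuple of float
        Inclusive period band to delete (default the circadian 18-30 h).
    """

    def __init__(self, dt_hours: float = 0.5,
                 band_hours=CIRCADIAN_BAND_HOURS):
        self.dt_hours = dt_hours
        self.band_hours = band_hours

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < 4:
            raise ValueError("need at least 4 samples per series")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            notch_filter(row, self.dt_hours, self.band_hours) for row in X
        ])


@dataclass
class SpectrumSet:
    """Amplitude spectra of a set of cluster mean series."""

    periods_hours: np.ndarray
    amplitude: np.ndarray  # k x n_bins
    null_mean: np.ndarray
    null_upper: np.ndarray
    null_lower: np.ndarray
    band_flags: np.ndarray
    significant_circadian: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in range(self.amplitude.shape[0]):
            rows.append(pd.DataFrame({
                "cluster": c,
                "period_hours": self.periods_hours,
                "amplitude": self.amplitude[c],
                "null_mean": self.null_mean[c],
                "null_upper": self.null_upper[c],
                "null_lower": self.null_lower[c],
                "band": self.band_flags,
                "significant": self.amplitude[c] > self.null_upper[c],
            }))
        return pd.concat(rows, ignore_index=True)


def cluster_spectra(mean_series: np.ndarray, dt_hours: float,
                    band_hours=CIRCADIAN_BAND_HOURS) -> SpectrumSet:
    """Per-cluster spectra with their own white-noise lines.

    Noise lines are computed per cluster spectrum (each cluster gets its
    own null), and a cluster is flagged circadian-significant when any
    bin with period in ``band_hours`` exceeds its upper line.
    """
    mean_series = np.atleast_2d(np.asarray(mean_series, dtype=float))
    periods, _ = power_spectrum(mean_series[0], dt_hours)
    amps, means, uppers, lowers, sig = [], [], [], [], []
    for row in mean_series:
        _, amp = power_spectrum(row, dt_hours)
        m, u, l = noise_lines(amp)
        amps.append(amp)
        means.append(m)
        uppers.append(u)
        lowers.append(l)
        lo, hi = band_hours
        in_band = (periods >= lo) & (periods <= hi)
        sig.append(bool(in_band.any() and amp[in_band].max() > u))
    return SpectrumSet(
        periods_hours=periods,
        amplitude=np.vstack(amps),
        null_mean=np.asarray(means),
        null_upper=np.asarray(uppers),
        null_lower=np.asarray(lowers),
        band_flags=band_classification(periods, band_hours),
        significant_circadian=np.asarray(sig, dtype=bool),
    )
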