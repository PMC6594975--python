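"""Fourier extraction of the complex response at the stimulus frequency.

The spectrum convention follows the analysis it reimplements: forward
transform with the e^(-i omega t) kernel, DC omitted, multiplied by 2 for
the single-sided spectrum and divided by the number of samples — so an
input a*cos(2 pi k n/N + phi) yields modulus a and angle phi at bin k.
Sample index n corresponds to scan time n*TR; the TR-center (+TR/2)
slice-timing correction is applied exactly once, downstream, when phase is
converted to delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import ScanTimeSeries

__all__ = [
    "ComplexResponse",
    "CycleAverage",
    "spectrum",
    "response_at_frequency",
    "flip_phase_180",
    "cycle_average",
]


@dataclass(frozen=True)
class ComplexResponse:
    """The complex value at one frequency bin for one participant x ROI x condition."""

    real: float
    imag: float
    frequency_index: int
    participant: str = ""
    roi: str = ""
    condition: str = ""

    def __post_init__(self):
        if self.frequency_index < 1:
            raise ValueError("frequency_index must be >= 1 (DC is omitted)")

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.real, self.imag))

    @property
    def phase(self) -> float:
        """Angle in (-pi, pi]."""
        return float(np.angle(complex(self.real, self.imag)))


@dataclass
class CycleAverage:
    """Per-position mean and SEM over one stimulus cycle.

    ``sample_times`` are at TR centers (TR/2, 3TR/2, ...) relative to
    A-block onset, which is where cycle averages are conventionally plotted.
    """

    mean: np.ndarray
    sem: np.ndarray
    sample_times: np.ndarray
    n_per_position: np.ndarray

    def __post_init__(self):
        if not (len(self.mean) == len(self.sem) == len(self.sample_times)
                == len(self.n_per_position)):
            raise ValueError("cycle-average arrays must share length")


def spectrum(series) -> np.ndarray:
    """Amplitude-scaled single-sided complex spectrum, DC omitted.

    Returns bins 1..floor(N/2) of ``2/N * FFT``; index 0 of the returned
    array is 1 cycle per scan.  NaNs are rejected — NaN padding is legal
    only in :func:`cycle_average`.
    """
    x = series.single_unit() if isinstance(series, ScanTimeSeries) else np.asarray(series, float)
    if x.ndim != 1:
        raise ValueError("spectrum expects a single-unit series")
    if np.isnan(x).any():
        raise ValueError("NaNs are not allowed in spectral input")
    n = x.size
    return 2.0 / n * np.fft.fft(x)[1:n // 2 + 1]


def response_at_frequency(series, k: int = 10, **labels) -> ComplexResponse:
    """The complex value at ``k`` cycles per scan (the stimulus frequency)."""
    x = series.single_unit() if isinstance(series, ScanTimeSeries) else np.asarray(series, float)
    n = x.size
    if not (1 <= k < n / 2):
        raise ValueError(f"frequency index {k} out of range [1, {n / 2})")
    spec = spectrum(x)
    val = spec[k - 1]
    if isinstance(series, ScanTimeSeries):
        labels.setdefault("participant", series.participant)
        labels.setdefault("roi", "")
        labels.setdefault("condition", series.condition)
    return ComplexResponse(real=float(val.real), imag=float(val.imag),
                           frequency_index=k, **labels)


def flip_phase_180(cr: ComplexResponse) -> ComplexResponse:
    """Rotate the complex response by 180 degrees (A/B block-order correction).

    Used when the block order of a condition was reversed at acquisition:
    negating both components shifts the recovered delay by half a period
    while leaving the amplitude unchanged.  Involutive.
    """
    return ComplexResponse(real=-cr.real, imag=-cr.imag,
                           frequency_index=cr.frequency_index,
                           participant=cr.participant, roi=cr.roi,
                           condition=cr.condition)


def cycle_average(series, samples_per_cycle: int, nan_pad: int = 0,
                  tr_seconds: float = 2.0) -> CycleAverage:
    """Fold a series into stimulus cycles and average per cycle position.

    ``nan_pad`` NaN samples are prepended first — the device used to keep
    cycle positions aligned for a condition whose block order was reversed
    (its series effectively starts half a cycle late).  After padding, only
    complete cycles are folded, so a trailing partial cycle is dropped; with
    the standard 6-sample pad on a 10-cycle series, positions 0-5 are
    averaged over 9 cycles and positions 6-11 over 10.  NaNs are ignored
    position-wise in both mean and SEM; a position with no finite sample
    at all yields NaN with a warning.
    """
    if isinstance(series, ScanTimeSeries):
        tr_seconds = series.tr_seconds
        x = series.single_unit()
    else:
        x = np.asarray(series, dtype=float)
    if x.size % samples_per_cycle != 0:
        raise ValueError(
            f"length {x.size} not divisible by {samples_per_cycle}")
    x = np.concatenate([np.full(nan_pad, np.nan), x])
    n_cycles = x.size // samples_per_cycle
    folded = x[:n_cycles * samples_per_cycle].reshape(-1, samples_per_cycle)
    n_obs = np.sum(np.isfinite(folded), axis=0)
    if (n_obs == 0).any():
        warnings.warn("cycle position(s) with no finite samples", RuntimeWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(folded, axis=0)
        sd = np.nanstd(folded, axis=0, ddof=1)
    sem = np.where(n_obs > 0, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    times = (np.arange(samples_per_cycle) + 0.5) * tr_seconds
    return CycleAverage(mean=mean, sem=sem, sample_times=times,
                        n_per_position=n_obs)
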