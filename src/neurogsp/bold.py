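"""BOLD time-series preprocessing.

Regional resting-state BOLD series (n regions × T timepoints, repetition
time TR seconds) pass through a fixed four-stage pipeline before any graph
filtering:

1. ``trim_initial`` — discard the first 18 s (scanner initialization
   transient; floor(18/TR) = 9 frames at TR = 2 s, 154 → 145 timepoints);
2. ``detrend`` — remove the per-region least-squares linear trend and
   constant offset;
3. ``bandpass`` — retain temporal frequencies in [0.009, 0.1] Hz with a
   hard (brick-wall) real-FFT bin mask, inclusive bounds;
4. ``zscore`` — per-region standardization to mean 0, sample SD 1
   (denominator T−1).

Each series carries a ``stage`` tag and stages may only be applied in
order (idempotent reapplication and skipping forward are allowed; going
backwards is an error), so a filtered-energy table is always computed from
identically prepared signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

STAGES = ("raw", "trimmed", "detrended", "bandpassed", "zscored")
_RANK = {s: i for i, s in enumerate(STAGES)}


class StageError(ValueError):
    """A preprocessing stage applied out of pipeline order."""


class ZeroVarianceError(ValueError):
    """A region has zero temporal variance and cannot be z-scored."""


@dataclass(frozen=True)
class BoldSeries:
    """Regional BOLD time series with provenance.

    ``values`` is an n×T float matrix (rows follow ``region_labels``),
    ``tr_seconds`` the repetition time (2.0 s in the source study).
    """

    values: np.ndarray = field(repr=False)
    tr_seconds: float
    region_labels: tuple
    subject_id: str = "subject"
    stage: str = "raw"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {v.shape}")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite BOLD values")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {v.shape[0]} regions"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds


def _check_stage(s: BoldSeries, target: str):
    if _RANK[s.stage] > _RANK[target]:
        raise StageError(
            f"cannot apply {target!r} to a series already at stage {s.stage!r}"
        )


def trim_initial(s: BoldSeries, discard_seconds: float = 18.0) -> BoldSeries:
    """Drop the first floor(discard_seconds/TR) frames."""
    _check_stage(s, "trimmed")
    if discard_seconds < 0:
        raise ValueError("discard_seconds must be nonnegative")
    if discard_seconds >= s.duration_seconds:
        raise ValueError(
            f"discard of {discard_seconds} s >= series duration "
            f"{s.duration_seconds} s"
        )
    k = int(np.floor(discard_seconds / s.tr_seconds))
    return replace(s, values=s.values[:, k:], stage="trimmed")


def detrend(s: BoldSeries) -> BoldSeries:
    """Subtract the per-region least-squares line a·t + b."""
    _check_stage(s, "detrended")
    if s.n_timepoints < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    out = _signal.detrend(s.values, axis=1, type="linear")
    return replace(s, values=out, stage="detrended")


def bandpass(s: BoldSeries, f_lo: float = 0.009, f_hi: float = 0.1) -> BoldSeries:
    """Brick-wall temporal band-pass via a real-FFT bin mask.

    Frequency bins with f_lo ≤ f ≤ f_hi (inclusive) are retained, all
    others (including DC when f_lo > 0) are zeroed.
    """
    _check_stage(s, "bandpassed")
    nyquist = 0.5 / s.tr_seconds
    if not (0 <= f_lo < f_hi <= nyquist):
        raise ValueError(
            f"invalid band [{f_lo}, {f_hi}] Hz for Nyquist {nyquist} Hz"
        )
    T = s.n_timepoints
    freqs = np.fft.rfftfreq(T, d=s.tr_seconds)
    spec = np.fft.rfft(s.values, axis=1)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=T, axis=1)
    return replace(s, values=out, stage="bandpassed")


def zscore(s: BoldSeries) -> BoldSeries:
    """Standardize each region to mean 0, sample SD 1 (ddof=1)."""
    _check_stage(s, "zscored")
    mu = s.values.mean(axis=1, keepdims=True)
    sd = s.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ZeroVarianceError(
            f"zero-variance region(s): "
            f"{', '.join(s.region_labels[i] for i in flat[:5])}"
        )
    return replace(s, values=(s.values - mu) / sd, stage="zscored")


def preprocess(
    s: BoldSeries,
    discard_seconds: float = 18.0,
    f_lo: float = 0.009,
    f_hi: float = 0.1,
) -> BoldSeries:
    """Run the full pipeline trim → detrend → bandpass → zscore."""
    return zscore(bandpass(detrend(trim_initial(s, discard_seconds)), f_lo, f_hi))
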