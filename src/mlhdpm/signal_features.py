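"""Feature extraction from physiological signals.

Covers amplitude and distortion features of a voltage trace (peak voltage,
total harmonic distortion, zero-crossing rate), occupancy-grid entropy and
energy, and heart-rate-variability statistics of an RR-interval series
(instantaneous heart rate, successive-difference mean/SD, RMSSD).

Two of the source formulas are dimensionally anomalous as printed — the
entropy sums P/ln(P) instead of -P·ln(P), and the successive-difference RMS
takes the square root of a *signed* sum, which can be negative.  Both are
provided verbatim behind an ``as_printed`` mode for traceability, with the
standard corrected forms (``shannon``, ``rmssd``) as the defaults used by the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .records_io import DomainError


@dataclass
class SignalSeries:
    """Uniformly sampled voltage trace (arbitrary units)."""

    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 1:
            raise DomainError("signal must be 1-D")
        if self.V.size and not np.all(np.isfinite(self.V)):
            raise DomainError("signal contains non-finite samples")


@dataclass
class HarmonicSpec:
    """Harmonic component magnitudes plus the fundamental/filter power P_ff."""

    HC: np.ndarray
    P_ff: float

    def __post_init__(self) -> None:
        self.HC = np.asarray(self.HC, dtype=float)
        if np.any(self.HC < 0):
            raise DomainError("harmonic magnitudes must be nonnegative")
        if self.P_ff == 0:
            raise DomainError("P_ff must be nonzero")


@dataclass
class RRSeries:
    """Successive inter-beat (RR) intervals in seconds."""

    RR: np.ndarray

    def __post_init__(self) -> None:
        self.RR = np.asarray(self.RR, dtype=float)
        if self.RR.ndim != 1:
            raise DomainError("RR series must be 1-D")
        if np.any(self.RR <= 0):
            raise DomainError("RR intervals must be positive")

    @property
    def M(self) -> int:
        return self.RR.size


@dataclass
class GridDistribution:
    """Nonnegative cell probabilities summing to 1 (within 1e-9)."""

    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise DomainError("cell probabilities must lie in [0, 1]")
        if abs(self.P.sum() - 1.0) > 1e-9:
            raise DomainError("cell probabilities must sum to 1")


@dataclass
class SignalFeatures:
    """Bundle of the extracted features for one subject/segment."""

    v_max: float
    thd: float | None
    heart_rate: float
    zcr: float
    entropy: float | None
    energy: float | None
    sd_rr: float
    rms_succ: float


def max_voltage(s: SignalSeries) -> float:
    """Peak sample value of the trace."""
    if s.V.size < 1:
        raise DomainError("max_voltage needs at least one sample")
    return float(np.max(s.V))


def total_harmonic_distortion(h: HarmonicSpec) -> float:
    """Sum of harmonic magnitudes over the fundamental/filter power."""
    return float(np.sum(h.HC) / h.P_ff)


def heart_rate(rr_t: float) -> float:
    """Instantaneous heart rate (bpm) from one RR interval in seconds."""
    if rr_t <= 0:
        raise DomainError("RR interval must be positive")
    return 60.0 / rr_t


def zero_crossing_rate(s: SignalSeries) -> float:
    """Fraction of adjacent sample pairs with a strict sign change.

    A zero-valued sample never produces a crossing (sign change is strict),
    so the rate is invariant under positive rescaling of the signal.
    """
    if s.V.size < 2:
        raise DomainError("zero_crossing_rate needs at least two samples")
    signs = np.sign(s.V)
    changes = signs[:-1] * signs[1:] < 0
    return float(np.count_nonzero(changes)) / (s.V.size - 1)


def grid_entropy(dist: GridDistribution,
                 mode: Literal["as_printed", "shannon"] = "shannon") -> float:
    """Entropy of an occupancy grid.

    ``shannon`` (default): -Σ P·ln(P).  ``as_printed``: Σ P/ln(P), the
    verbatim source form (negative for all non-degenerate distributions).
    Zero cells contribute 0 in both modes (limit convention); a cell equal to
    1 makes the printed form's denominator ln(1)=0 and raises.
    """
    P = dist.P[dist.P > 0]
    if mode == "shannon":
        return float(-np.sum(P * np.log(P)))
    if mode == "as_printed":
        if np.any(P == 1.0):
            raise DomainError("as_printed entropy undefined for a cell equal to 1")
        return float(np.sum(P / np.log(P)))
    raise ValueError(f"unknown entropy mode {mode!r}")


def grid_energy(dist: GridDistribution) -> float:
    """Σ P², in (0, 1]; equals 1 iff the mass sits on a single cell."""
    return float(np.sum(dist.P ** 2))


def _successive_diffs(rr: RRSeries) -> np.ndarray:
    if rr.M < 2:
        raise DomainError("need at least two RR intervals")
    return np.diff(rr.RR)


def rr_deviation_mean(rr: RRSeries) -> float:
    """Mean successive difference k = Σ(RR_x - RR_{x-1}) / (M-1)."""
    d = _successive_diffs(rr)
    return float(np.sum(d) / (rr.M - 1))


def rr_sd(rr: RRSeries) -> float:
    """(1/M) · sqrt(Σ (successive difference - k)²) with k the mean difference."""
    d = _successive_diffs(rr)
    k = np.sum(d) / (rr.M - 1)
    return float(np.sqrt(np.sum((d - k) ** 2)) / rr.M)


def rr_rms_successive(rr: RRSeries,
                      mode: Literal["as_printed", "rmssd"] = "rmssd") -> float:
    """Root-mean-square of successive RR differences.

    ``rmssd`` (default): sqrt(Σ diff² / (M-1)), the standard HRV statistic.
    ``as_printed``: sqrt(Σ diff / (M-1)) verbatim, which is undefined when the
    signed sum is negative and raises in that case.
    """
    d = _successive_diffs(rr)
    if mode == "rmssd":
        return float(np.sqrt(np.sum(d ** 2) / (rr.M - 1)))
    if mode == "as_printed":
        radicand = np.sum(d) / (rr.M - 1)
        if radicand < 0:
            raise DomainError("as_printed RMS undefined: negative radicand")
        return float(np.sqrt(radicand))
    raise ValueError(f"unknown RMS mode {mode!r}")


def extract_features(signal: SignalSeries | None = None,
                     rr: RRSeries | None = None,
                     harmonics: HarmonicSpec | None = None,
                     grid: GridDistribution | None = None) -> SignalFeatures:
    """Compute the full feature bundle from whichever inputs are available.

    The RR series drives heart rate (from the mean interval) and the
    variability statistics; the voltage trace drives peak and crossing
    features.  Missing optional inputs yield ``None`` features.
    """
    if rr is None:
        raise DomainError("an RR series is required")
    mean_rr = float(np.mean(rr.RR))
    return SignalFeatures(
        v_max=max_voltage(signal) if signal is not None else float("nan"),
        thd=total_harmonic_distortion(harmonics) if harmonics is not None else None,
        heart_rate=heart_rate(mean_rr),
        zcr=zero_crossing_rate(signal) if signal is not None else float("nan"),
        entropy=grid_entropy(grid) if grid is not None else None,
        energy=grid_energy(grid) if grid is not None else None,
        sd_rr=rr_sd(rr),
        rms_succ=rr_rms_successive(rr),
    )


def read_signal(path: str | Path) -> SignalSeries:
    """Read a plain-text trace, one voltage sample per line."""
    values = _read_column(path)
    return SignalSeries(values)


def read_rr(path: str | Path) -> RRSeries:
    """Read a plain-text RR series in seconds, one interval per line."""
    values = _read_column(path)
    return RRSeries(values)


def _read_column(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    vals: list[float] = []
    for line in lines:
        line = line.strip()
        if line:
            vals.append(float(line))
    return np.asarray(vals, dtype=float)
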