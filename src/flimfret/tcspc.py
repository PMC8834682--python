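"""Forward model of a TCSPC measurement.

A time-correlated single-photon-counting (TCSPC) instrument histograms photon
arrival times relative to a periodic excitation pulse.  The expected histogram
is a multi-exponential fluorescence decay, summed over preceding excitation
periods (periodic "wrap-around"), convolved with the instrument response
function (IRF), plus a uniform background.  This module provides that forward
model on a discrete channel grid; everything downstream (simulation, fitting)
builds on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, InvalidModelError

__all__ = [
    "FWHM_TO_SIGMA",
    "AcquisitionConfig",
    "ExponentialComponent",
    "DecayModel",
    "TCSPCHistogram",
    "decay_curve",
    "gaussian_irf",
    "expected_counts",
    "wrap_sensitive",
]

#: Conversion factor sigma = FWHM * FWHM_TO_SIGMA for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Per-period decay factors below this are dropped from the wrap summation.
_WRAP_TRUNCATION = 1e-12

#: Lifetimes with e^(-window/tau) above this leave a visible (>1e-6 of peak)
#: wrap-around tail and are flagged as wrap-sensitive.
_WRAP_SENSITIVE_LEVEL = 1e-6


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry of one TCSPC measurement.

    The excitation window is tied to the laser repetition rate
    (``window_ns = 1000 / repetition_rate_mhz``; 25 ns at 40 MHz) and divided
    into ``n_channels`` equal-width channels.  The IRF is modeled as a
    Gaussian of the given FWHM centered at ``irf_center_ns``.
    """

    repetition_rate_mhz: float = 40.0
    n_channels: int = 256
    irf_center_ns: float = 2.0
    irf_fwhm_ns: float = 0.15
    background_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.repetition_rate_mhz <= 0:
            raise InvalidConfigError("repetition_rate_mhz must be positive")
        if int(self.n_channels) != self.n_channels or self.n_channels < 2:
            raise InvalidConfigError("n_channels must be an integer >= 2")
        if self.irf_fwhm_ns <= 0:
            raise InvalidConfigError("irf_fwhm_ns must be positive")
        if not 0.0 <= self.irf_center_ns < self.window_ns:
            raise InvalidConfigError(
                f"irf_center_ns={self.irf_center_ns} outside the "
                f"[0, {self.window_ns}) excitation window"
            )
        if not 0.0 <= self.background_fraction < 1.0:
            raise InvalidConfigError("background_fraction must be in [0, 1)")

    @property
    def window_ns(self) -> float:
        """Time span of one excitation period in ns."""
        return 1000.0 / self.repetition_rate_mhz

    @property
    def channel_width_ns(self) -> float:
        return self.window_ns / self.n_channels

    def channel_centers(self) -> np.ndarray:
        """Midpoints of the channels in ns (the model's sampling grid)."""
        dt = self.channel_width_ns
        return (np.arange(self.n_channels) + 0.5) * dt

    def to_dict(self) -> dict:
        return {
            "repetition_rate_mhz": self.repetition_rate_mhz,
            "n_channels": int(self.n_channels),
            "irf_center_ns": self.irf_center_ns,
            "irf_fwhm_ns": self.irf_fwhm_ns,
            "background_fraction": self.background_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


@dataclass(frozen=True)
class ExponentialComponent:
    """One exponential decay species: weight ``amplitude``, lifetime ``tau``."""

    amplitude: float
    lifetime_ns: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidModelError("component amplitude must be >= 0")
        if self.lifetime_ns <= 0:
            raise InvalidModelError("component lifetime must be > 0")


@dataclass(frozen=True)
class DecayModel:
    """One- or two-exponential decay, components sorted by descending lifetime.

    In the FRET context the long-lifetime component is the unquenched donor
    (UD) and the short one the acceptor-quenched donor (QD).
    """

    components: tuple[ExponentialComponent, ...]
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise InvalidModelError("DecayModel supports 1 or 2 components")
        lifetimes = [c.lifetime_ns for c in comps]
        if any(b >= a for a, b in zip(lifetimes, lifetimes[1:])):
            raise InvalidModelError(
                "components must be strictly ordered by descending lifetime"
            )
        if sum(c.amplitude for c in comps) <= 0:
            raise InvalidModelError("total amplitude must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise InvalidModelError("background_fraction must be in [0, 1)")

    @property
    def lifetimes(self) -> tuple[float, ...]:
        return tuple(c.lifetime_ns for c in self.components)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(c.amplitude for c in self.components)


@dataclass
class TCSPCHistogram:
    """One ROI's photon-count decay curve plus acquisition metadata."""

    counts: np.ndarray
    config: AcquisitionConfig
    roi_id: str
    condition: str = ""
    compartment: str = "whole_cell"
    experiment_index: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) != self.config.n_channels:
            raise InvalidConfigError(
                f"counts length {counts.size} does not match "
                f"n_channels {self.config.n_channels}"
            )
        if np.any(counts < 0):
            raise InvalidConfigError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


def decay_curve(model: DecayModel, time_grid: Sequence[float]) -> np.ndarray:
    """Evaluate the bare multi-exponential kernel sum_i A_i exp(-t / tau_i).

    No IRF, wrap or background: this is the impulse response of the decay
    model on ``time_grid`` (ns, all >= 0).
    """
    if not isinstance(model, DecayModel):
        raise InvalidModelError("model must be a DecayModel")
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time_grid values must be >= 0")
    out = np.zeros_like(t)
    for comp in model.components:
        out += comp.amplitude * np.exp(-t / comp.lifetime_ns)
    return out


def gaussian_irf(config: AcquisitionConfig) -> np.ndarray:
    """Discrete Gaussian IRF kernel over channels, normalized to sum 1.

    Kernel element m is the Gaussian evaluated at a delay of m whole
    channels (circular mod-window distance to ``irf_center_ns``), so that
    convolving a channel-center-sampled decay with this kernel keeps the
    time axis aligned: the convolved peak sits at ``irf_center_ns`` with no
    half-channel offset, and moving the center by k channels shifts the
    kernel exactly k elements.
    """
    sigma = config.irf_fwhm_ns * FWHM_TO_SIGMA
    t = np.arange(config.n_channels) * config.channel_width_ns
    window = config.window_ns
    delta = (t - config.irf_center_ns + window / 2.0) % window - window / 2.0
    kernel = np.exp(-0.5 * (delta / sigma) ** 2)
    total = kernel.sum()
    if total <= 0:
        raise InvalidConfigError("IRF kernel vanished on the channel grid")
    return kernel / total


def _wrap_factor(lifetime_ns: float, window_ns: float) -> float:
    """Truncated geometric factor for summation over preceding periods.

    A decay excited every ``window_ns`` contributes
    sum_m exp(-(t + m*T)/tau) = exp(-t/tau) * sum_m q^m with q = e^(-T/tau).
    The sum is truncated once q^m < 1e-12.
    """
    q = np.exp(-window_ns / lifetime_ns)
    if q < _WRAP_TRUNCATION:
        return 1.0
    if q >= 1.0 - 1e-12:  # pathological tau >> window; cap the summation
        q = 1.0 - 1e-12
    n_terms = int(np.ceil(np.log(_WRAP_TRUNCATION) / np.log(q)))
    return float((1.0 - q**n_terms) / (1.0 - q))


def wrap_sensitive(model: DecayModel, config: AcquisitionConfig) -> bool:
    """True if any lifetime leaves a wrap-around tail above 1e-6 of peak."""
    return any(
        np.exp(-config.window_ns / tau) > _WRAP_SENSITIVE_LEVEL
        for tau in model.lifetimes
    )


def expected_counts(
    model: DecayModel,
    config: AcquisitionConfig,
    total_photons: float,
    periodic_wrap: bool = True,
) -> np.ndarray:
    """Per-channel expected counts of the full TCSPC forward model.

    The decay (with per-component periodic wrap factors when ``periodic_wrap``)
    is sampled at channel centers, convolved with the Gaussian IRF
    (circularly when ``periodic_wrap``, linearly otherwise), mixed with a
    uniform background of weight ``model.background_fraction``, and rescaled
    so the vector sums exactly to ``total_photons``.
    """
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    t = config.channel_centers()
    n = config.n_channels
    decay = np.zeros(n)
    for comp in model.components:
        factor = (
            _wrap_factor(comp.lifetime_ns, config.window_ns)
            if periodic_wrap
            else 1.0
        )
        decay += comp.amplitude * factor * np.exp(-t / comp.lifetime_ns)

    if periodic_wrap:
        kernel = gaussian_irf(config)
        conv = np.fft.irfft(np.fft.rfft(decay) * np.fft.rfft(kernel), n=n)
    else:
        sigma = config.irf_fwhm_ns * FWHM_TO_SIGMA
        delays = np.arange(n) * config.channel_width_ns
        kernel = np.exp(-0.5 * ((delays - config.irf_center_ns) / sigma) ** 2)
        kernel /= kernel.sum()
        conv = np.convolve(decay, kernel)[:n]
    conv = np.clip(conv, 0.0, None)
    s = conv.sum()
    if s <= 0:
        raise InvalidModelError("forward model produced an empty decay")
    bg = model.background_fraction
    shape = (1.0 - bg) * conv / s + bg / n
    return total_photons * shape
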