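"""Peripheral auditory front end: ERB-spaced band profiles and positive spectral gradients.

The model's spectral cues live on a grid of auditory filter bands spaced by one
equivalent rectangular bandwidth (ERB) between 700 Hz and 18 kHz.  For a
direction-dependent transfer function (DTF) and a stimulus power spectrum, each
band yields the log of the average squared amplitude (dB); the rectified first
difference of that profile is the positive spectral gradient (PSG) profile the
template comparison operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "erb_number",
    "erb_number_inverse",
    "erb_bandwidth",
    "ErbBandGrid",
    "erb_band_centers",
    "SpectralProfile",
    "magnitude_profile",
    "GradientProfile",
    "psg",
]


def erb_number(f_hz):
    """Glasberg & Moore ERB-number scale E(f) = 21.4*log10(0.00437*f + 1)."""
    return 21.4 * np.log10(0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_inverse(erb):
    """Inverse of :func:`erb_number`: frequency in Hz at a given ERB number."""
    return (10.0 ** (np.asarray(erb, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth (Hz) at centre frequency ``f_hz``."""
    return 24.7 * (0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


@dataclass(frozen=True)
class ErbBandGrid:
    """Band centre frequencies spaced on the ERB-number scale.

    Attributes
    ----------
    center_frequencies
        Strictly increasing centre frequencies in Hz.
    step
        Spacing between adjacent centres in ERB-number units.
    """

    center_frequencies: np.ndarray
    step: float = 1.0

    def __post_init__(self):
        cf = np.asarray(self.center_frequencies, dtype=float)
        object.__setattr__(self, "center_frequencies", cf)
        if cf.ndim != 1 or cf.size < 1:
            raise ValueError("band grid needs at least one centre frequency")
        if cf.size > 1 and not np.all(np.diff(cf) > 0):
            raise ValueError("centre frequencies must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.center_frequencies.size

    @property
    def gradient_frequencies(self) -> np.ndarray:
        """Centre frequencies of the gradient bands b = 2..Nb."""
        return self.center_frequencies[1:]

    def band_edges(self) -> np.ndarray:
        """(Nb, 2) lower/upper edges of 1-ERB-wide rectangular windows."""
        cf = self.center_frequencies
        half = 0.5 * erb_bandwidth(cf)
        return np.column_stack([cf - half, cf + half])


def erb_band_centers(f_low: float = 700.0, f_high: float = 18000.0,
                     step: float = 1.0) -> ErbBandGrid:
    """Centre frequencies at equal steps on the ERB-number scale.

    The first centre sits at ``f_low``; further centres are added every
    ``step`` ERB-number units up to (and not beyond) ``f_high``.
    """
    if not (0.0 < f_low <= f_high):
        raise ValueError(f"invalid frequency range [{f_low}, {f_high}]")
    if step <= 0:
        raise ValueError("step must be positive")
    e_lo, e_hi = erb_number(f_low), erb_number(f_high)
    n = int(np.floor((e_hi - e_lo) / step + 1e-9)) + 1
    centers = erb_number_inverse(e_lo + step * np.arange(n))
    centers[0] = f_low  # kill round-trip rounding at the anchor
    return ErbBandGrid(centers, step=step)


@dataclass
class SpectralProfile:
    """Band magnitude profile ξ in dB for one ear and direction."""

    xi: np.ndarray
    grid: ErbBandGrid
    ear: str = "left"
    direction: tuple = (0.0, 0.0)  # (lateral deg, polar deg)

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.shape != (self.grid.n_bands,):
            raise ValueError("profile length must equal the number of bands")
        if not np.all(np.isfinite(self.xi)):
            raise ValueError("profile must be finite")


@dataclass
class GradientProfile:
    """Positive spectral gradient profile ξ̃ (dB) for bands b = 2..Nb."""

    xi_tilde: np.ndarray

    def __post_init__(self):
        self.xi_tilde = np.asarray(self.xi_tilde, dtype=float)
        if np.any(self.xi_tilde < 0):
            raise ValueError("PSG entries must be non-negative")


def magnitude_profile(frequencies: np.ndarray, dtf_magnitude: np.ndarray,
                      grid: ErbBandGrid, stimulus_power: np.ndarray | None = None,
                      ear: str = "left", direction=(0.0, 0.0)) -> SpectralProfile:
    """Band magnitude profile: 10*log10 of band-averaged squared amplitude.

    Parameters
    ----------
    frequencies
        Common frequency axis (Hz, ascending) of DTF and stimulus.
    dtf_magnitude
        Linear magnitude gain of the DTF on that axis.
    grid
        Band grid; each band averages over a 1-ERB-wide rectangular window.
    stimulus_power
        Stimulus power spectrum on the same axis; a flat unit spectrum
        (broadband white noise) when omitted.
    """
    f = np.asarray(frequencies, dtype=float)
    h = np.asarray(dtf_magnitude, dtype=float)
    if f.ndim != 1 or h.shape != f.shape:
        raise ValueError("dtf magnitude must match the frequency axis")
    p = np.ones_like(f) if stimulus_power is None else np.asarray(stimulus_power, float)
    if p.shape != f.shape:
        raise ValueError("stimulus power must match the frequency axis")
    power = h * h * p
    edges = grid.band_edges()
    if edges[0, 0] < f[0] - 1e-9 or edges[-1, 1] > f[-1] + 1e-9:
        raise ValueError(
            f"frequency axis [{f[0]:.1f}, {f[-1]:.1f}] Hz does not cover the "
            f"band windows [{edges[0, 0]:.1f}, {edges[-1, 1]:.1f}] Hz")
    xi = np.empty(grid.n_bands)
    for b, (lo, hi) in enumerate(edges):
        sel = (f >= lo) & (f <= hi)
        if not np.any(sel):
            raise ValueError(f"no spectral samples inside band {b} ({lo:.0f}-{hi:.0f} Hz)")
        xi[b] = 10.0 * np.log10(power[sel].mean())
    return SpectralProfile(xi, grid, ear=ear, direction=tuple(direction))


def psg(profile) -> GradientProfile:
    """Positive spectral gradient ξ̃[b] = max(ξ[b] − ξ[b−1], 0), b = 2..Nb."""
    xi = profile.xi if isinstance(profile, SpectralProfile) else np.asarray(profile, float)
    if xi.ndim != 1 or xi.size < 2:
        raise ValueError("PSG needs a profile with at least two bands")
    return GradientProfile(np.maximum(np.diff(xi), 0.0))
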