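"""Spectral weighting schemes over the gradient bands.

Five schemes are compared: Flat (uniform), NR (emphasis near the 8-kHz main
notch region), DT (emphasis near 6 kHz, from discrimination-task data), SV
(per-band spatial variance of the listener's own templates across polar
angle, at subject or group level), and LP (low-pass, exponentially decaying
weight toward high frequencies).  All schemes are non-negative and normalized
to unit sum on the gradient bands b = 2..Nb, so the weight scale never trades
off against the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TemplateSet, binaural_weight, BINAURAL_PHI_SCALE_DEG
from .peripheral import ErbBandGrid

__all__ = [
    "SCHEME_NAMES",
    "WeightingScheme",
    "SpatialVariance",
    "flat_scheme",
    "bump_scheme",
    "nr_scheme",
    "dt_scheme",
    "lp_scheme",
    "spatial_variance",
    "sv_weights",
    "group_sv_weights",
    "make_scheme",
]

SCHEME_NAMES = ("Flat", "NR", "DT", "SV", "LP")

NR_CENTER_HZ = 8000.0
DT_CENTER_HZ = 6000.0
BUMP_WIDTH_OCTAVES = 1.0
BUMP_FLOOR = 0.05
LP_DECAY_PER_OCTAVE = 0.5


@dataclass
class WeightingScheme:
    """Per-band weights w[b] on the gradient bands of an ERB grid."""

    name: str
    weights: np.ndarray
    grid: ErbBandGrid
    level: str = "group"           # "group" or "subject"
    lateral_plane: float | None = None   # SV only
    subject_id: str | None = None        # subject-level SV only

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.n_bands - 1,):
            raise ValueError("weights must cover the gradient bands (Nb-1)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")
        self.weights = w

    def to_frame(self) -> pd.DataFrame:
        """Two-column serialization: gradient-band centre (Hz) and weight."""
        return pd.DataFrame({"center_hz": self.grid.gradient_frequencies,
                             "weight": self.weights})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: ErbBandGrid,
                   name: str = "custom", **kw) -> "WeightingScheme":
        if not np.allclose(frame["center_hz"].to_numpy(),
                           grid.gradient_frequencies, rtol=1e-6):
            raise ValueError("table band centres do not match the grid")
        w = frame["weight"].to_numpy(dtype=float)
        return cls(name, w / w.sum(), grid, **kw)


def _normalized(name, raw, grid, **kw) -> WeightingScheme:
    raw = np.asarray(raw, dtype=float)
    return WeightingScheme(name, raw / raw.sum(), grid, **kw)


def flat_scheme(grid: ErbBandGrid) -> WeightingScheme:
    """Uniform weights — the original model's flat spectral weighting."""
    n = grid.n_bands - 1
    if n < 1:
        raise ValueError("grid must have at least two bands")
    return WeightingScheme("Flat", np.full(n, 1.0 / n), grid)


def bump_scheme(grid: ErbBandGrid, center: float, width: float = BUMP_WIDTH_OCTAVES,
                floor: float = BUMP_FLOOR, name: str = "bump") -> WeightingScheme:
    """Log-frequency Gaussian emphasis around ``center`` Hz over a small floor.

    w[b] ∝ floor + (1 − floor)·exp(−log2(f_b/center)² / (2·width²)).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not (0.0 <= floor < 1.0):
        raise ValueError("floor must be a fraction in [0, 1)")
    f = grid.gradient_frequencies
    if not (f[0] <= center <= f[-1]):
        raise ValueError(f"bump centre {center} Hz outside the grid span "
                         f"[{f[0]:.0f}, {f[-1]:.0f}] Hz")
    gauss = np.exp(-0.5 * (np.log2(f / center) / width) ** 2)
    return _normalized(name, floor + (1.0 - floor) * gauss, grid)


def nr_scheme(grid: ErbBandGrid) -> WeightingScheme:
    """Notch-region scheme: emphasis around 8 kHz."""
    return bump_scheme(grid, NR_CENTER_HZ, name="NR")


def dt_scheme(grid: ErbBandGrid) -> WeightingScheme:
    """Discrimination-task scheme: emphasis around 6 kHz."""
    return bump_scheme(grid, DT_CENTER_HZ, name="DT")


def lp_scheme(grid: ErbBandGrid,
              decay: float = LP_DECAY_PER_OCTAVE) -> WeightingScheme:
    """Low-pass scheme: weight decays by ``decay`` per octave above 700 Hz."""
    if not (0.0 < decay < 1.0):
        raise ValueError("decay must be in (0, 1) for a decreasing scheme")
    f = grid.gradient_frequencies
    return _normalized("LP", decay ** np.log2(f / 700.0), grid)


@dataclass
class SpatialVariance:
    """Binaurally combined per-band template variance ν for one sagittal plane."""

    nu: np.ndarray
    grid: ErbBandGrid
    lateral_plane: float
    subject_id: str | None = None
    per_ear: dict = field(default_factory=dict)   # diagnostic: v_L/v_R per plane

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        if np.any(self.nu < 0):
            raise ValueError("spatial variance must be non-negative")


def spatial_variance(templates: TemplateSet, lateral_plane: float = 0.0,
                     binaural_alpha: float | None = None,
                     phi_scale: float = BINAURAL_PHI_SCALE_DEG) -> SpatialVariance:
    """Per-band variance of the PSG templates across polar angle, ear-combined.

    ν[ϕk,b] = 0.5·(v_L[ϕk]·α + v_R[ϕk]·(1−α) + v_L[ϕ−k]·(1−α) + v_R[ϕ−k]·α)

    where v is the population variance of ξ̃r over θ and α = α(ϕk) is the
    signed left-ear binaural weight of the plane (so the ipsilateral ear is
    upweighted).  Since α(ϕ−k) = 1 − α(ϕk), averaging a plane with its
    mirror makes ν[ϕk] = ν[ϕ−k] exact, i.e. symmetric weights.
    """
    # evaluate on the positive plane regardless of the sign of the request,
    # so ν(+ϕ) and ν(−ϕ) are the same computation and agree bit-exactly
    phi = abs(float(lateral_plane))
    try:
        pk = templates.plane(phi)
        pm = templates.plane(-phi)
    except KeyError as exc:
        raise ValueError(f"missing plane or mirror plane at ±{phi}° needed "
                         "for symmetric spatial variance") from exc
    if binaural_alpha is None:
        binaural_alpha = binaural_weight(phi, phi_scale)
    a = float(binaural_alpha)
    v = {("L", +1): pk.left.var(axis=0), ("R", +1): pk.right.var(axis=0),
         ("L", -1): pm.left.var(axis=0), ("R", -1): pm.right.var(axis=0)}
    nu = 0.5 * (v[("L", +1)] * a + v[("R", +1)] * (1 - a)
                + v[("L", -1)] * (1 - a) + v[("R", -1)] * a)
    return SpatialVariance(nu, templates.grid, phi,
                           subject_id=templates.subject_id, per_ear=v)


def sv_weights(nu: SpatialVariance) -> WeightingScheme:
    """Subject-level SV scheme: ν normalized by its band sum."""
    total = nu.nu.sum()
    if total <= 0:
        raise ValueError("all-zero spatial variance carries no spatial information")
    return WeightingScheme("SV", nu.nu / total, nu.grid, level="subject",
                           lateral_plane=nu.lateral_plane,
                           subject_id=nu.subject_id)


def group_sv_weights(subject_weights: list[WeightingScheme]) -> WeightingScheme:
    """Group-level SV scheme: arithmetic mean of subject-level weights."""
    if not subject_weights:
        raise ValueError("need at least one subject-level scheme")
    first = subject_weights[0]
    for s in subject_weights[1:]:
        if s.weights.size != first.weights.size:
            raise ValueError("schemes must share the band grid")
        if (s.lateral_plane is None) != (first.lateral_plane is None) or (
                s.lateral_plane is not None
                and not np.isclose(s.lateral_plane, first.lateral_plane)):
            raise ValueError("schemes must share the lateral plane")
    mean = np.mean([s.weights for s in subject_weights], axis=0)
    return WeightingScheme("SV", mean / mean.sum(), first.grid, level="group",
                           lateral_plane=first.lateral_plane)


def make_scheme(name: str, grid: ErbBandGrid,
                templates: TemplateSet | list[TemplateSet] | None = None,
                lateral_plane: float = 0.0, sv_level: str = "group",
                **kw) -> WeightingScheme:
    """Build a scheme by name; SV needs templates (one set or a cohort list)."""
    key = name.upper() if name.upper() in ("NR", "DT", "SV", "LP") else name.capitalize()
    if key == "Flat":
        return flat_scheme(grid)
    if key == "NR":
        return nr_scheme(grid)
    if key == "DT":
        return dt_scheme(grid)
    if key == "LP":
        return lp_scheme(grid, **kw)
    if key == "SV":
        if templates is None:
            raise ValueError("SV scheme requires template sets")
        tpls = templates if isinstance(templates, (list, tuple)) else [templates]
        subj = [sv_weights(spatial_variance(t, lateral_plane)) for t in tpls]
        if sv_level == "subject":
            if len(subj) != 1:
                raise ValueError("subject-level SV needs exactly one template set")
            return subj[0]
        return group_sv_weights(subj)
    raise ValueError(f"unknown scheme name {name!r}")
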