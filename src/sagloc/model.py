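"""Template-matching model of sagittal-plane localization.

Maps a target's positive-spectral-gradient (PSG) profile and a listener's
internal templates to a probability mass vector (PMV) over response polar
angles.  The pipeline per target is

    weighted spectral distance d[θ]  (per ear)
      → sigmoidal similarity ς[θ] with selectivity Γ and sensitivity S
      → binaural combination (ipsilateral ear weighted more)
      → sensorimotor scatter (wrapped-Gaussian smear of SD ε degrees)
      → normalization to a PMV over polar-angle bins.

Polar angle θ is circular on [−90°, 270°), running front-below → up →
rear-below within a sagittal plane; the lateral angle ϕ selects the plane
(positive ϕ = left of the median plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .peripheral import ErbBandGrid, GradientProfile

__all__ = [
    "DEFAULT_POLAR_GRID",
    "BINAURAL_PHI_SCALE_DEG",
    "ModelParams",
    "PlaneTemplates",
    "TemplateSet",
    "DistanceProfile",
    "PMV",
    "binaural_weight",
    "distance_profile",
    "similarity",
    "binaural_combine",
    "gaussian_kernel",
    "sensorimotor_smear",
    "to_pmv",
    "PmvPredictor",
    "predict_pmv",
]

#: Regular 5° response grid over the polar dimension (72 bins).
DEFAULT_POLAR_GRID = np.arange(-90.0, 270.0, 5.0)

#: Scale (degrees) of the logistic binaural weighting in lateral angle.
BINAURAL_PHI_SCALE_DEG = 13.0


@dataclass(frozen=True)
class ModelParams:
    """Listener-specific model parameters.

    gamma : degree of selectivity Γ (> 0), slope of the similarity sigmoid.
    s : sensitivity S (dimensionless), horizontal shift of the sigmoid.
    epsilon : sensorimotor scatter ε in degrees (> 0), SD of the response smear.
    """

    gamma: float
    s: float
    epsilon: float

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class PlaneTemplates:
    """Per-ear PSG templates over a polar grid within one sagittal plane."""

    lateral: float
    polar: np.ndarray            # (K,), strictly increasing, within [-90, 270)
    left: np.ndarray             # (K, Nb-1) PSG profiles, left ear
    right: np.ndarray            # (K, Nb-1) PSG profiles, right ear

    def __post_init__(self):
        self.polar = np.asarray(self.polar, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if not np.all(np.diff(self.polar) > 0):
            raise ValueError("polar grid must be strictly increasing")
        if self.polar.min() < -90 or self.polar.max() >= 270:
            raise ValueError("polar angles must lie in [-90, 270)")
        k = self.polar.size
        if self.left.shape[0] != k or self.right.shape[0] != k:
            raise ValueError("template arrays must match the polar grid")
        if self.left.shape != self.right.shape:
            raise ValueError("both ears must share the template shape")


@dataclass
class TemplateSet:
    """A listener's internal templates: PSG profiles per plane, ear, direction."""

    subject_id: str
    grid: ErbBandGrid
    planes: dict[float, PlaneTemplates] = field(default_factory=dict)

    @property
    def lateral_planes(self) -> list[float]:
        return sorted(self.planes)

    def plane(self, lateral: float, atol: float = 1e-6) -> PlaneTemplates:
        for lat, pl in self.planes.items():
            if abs(lat - lateral) <= atol:
                return pl
        raise KeyError(f"no templates for lateral plane {lateral}°"
                       f" (available: {self.lateral_planes})")


@dataclass
class DistanceProfile:
    """Weighted spectral distances d[θ] between target and templates, one ear."""

    polar: np.ndarray
    d: np.ndarray
    ear: str

    def __post_init__(self):
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class PMV:
    """Discrete probability distribution over response polar angles."""

    polar: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.polar = np.asarray(self.polar, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < -1e-12) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("PMV must be non-negative and sum to 1")

    def entropy(self) -> float:
        p = self.p[self.p > 0]
        return float(-(p * np.log(p)).sum())

    def mode(self) -> float:
        return float(self.polar[int(np.argmax(self.p))])


def binaural_weight(lateral_deg: float,
                    phi_scale: float = BINAURAL_PHI_SCALE_DEG) -> float:
    """Left-ear weight of the binaural combination at lateral angle ϕ.

    Logistic in the signed lateral angle (positive ϕ = left), so the
    ipsilateral ear always receives the larger weight; exactly 0.5 on the
    median plane.
    """
    return float(expit(lateral_deg / phi_scale))


def _resolve_weights(scheme, n_gradient_bands: int) -> np.ndarray:
    w = np.asarray(getattr(scheme, "weights", scheme), dtype=float)
    if w.shape != (n_gradient_bands,):
        raise ValueError(
            f"scheme has {w.size} weights but templates have "
            f"{n_gradient_bands} gradient bands")
    return w


def distance_profile(templates: TemplateSet, target: GradientProfile, scheme,
                     ear: str = "left", lateral_plane: float = 0.0) -> DistanceProfile:
    """d[θ] = Σ_b |ξ̃r[θ,b] − ξ̃t[b]| · w[b] for one ear within one plane."""
    plane = templates.plane(lateral_plane)
    tpl = plane.left if ear == "left" else plane.right
    xt = np.asarray(target.xi_tilde, dtype=float)
    if xt.shape != (tpl.shape[1],):
        raise ValueError("target gradient bands do not match the templates")
    w = _resolve_weights(scheme, tpl.shape[1])
    d = np.abs(tpl - xt[None, :]) @ w
    return DistanceProfile(plane.polar, d, ear)


def similarity(d, gamma: float, s: float) -> np.ndarray:
    """Similarity ς = 1 − (1 + exp(−Γ·(d − S)))⁻¹, strictly decreasing in d."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    darr = d.d if isinstance(d, DistanceProfile) else np.asarray(d, dtype=float)
    # 1 - logistic(x) == logistic(-x); expit is overflow-safe
    return expit(-gamma * (darr - s))


def binaural_combine(sigma_left: np.ndarray, sigma_right: np.ndarray,
                     lateral_angle: float,
                     phi_scale: float = BINAURAL_PHI_SCALE_DEG) -> np.ndarray:
    """α-weighted sum of the per-ear similarity profiles."""
    sl = np.asarray(sigma_left, float)
    sr = np.asarray(sigma_right, float)
    if sl.shape != sr.shape:
        raise ValueError("per-ear profiles must share a polar grid")
    w_left = binaural_weight(lateral_angle, phi_scale)
    return w_left * sl + (1.0 - w_left) * sr


def _check_regular_circular(polar_grid: np.ndarray) -> float:
    grid = np.asarray(polar_grid, dtype=float)
    steps = np.diff(grid)
    if grid.size < 2 or not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("smearing requires a regular polar grid")
    step = steps[0]
    if not np.isclose(grid.size * step, 360.0, atol=1e-6):
        raise ValueError("smearing requires the grid to cover the full circle")
    return step


def gaussian_kernel(epsilon: float, polar_grid: np.ndarray) -> np.ndarray:
    """Wrapped-Gaussian kernel (period 360°) of SD ε on a regular grid, sum 1."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    step = _check_regular_circular(polar_grid)
    k = np.asarray(polar_grid).size
    offsets = step * np.arange(k)
    wraps = offsets[None, :] + 360.0 * np.arange(-3, 4)[:, None]
    kernel = np.exp(-0.5 * (wraps / epsilon) ** 2).sum(axis=0)
    return kernel / kernel.sum()


def _circulant_smear(profiles: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution of row profiles with the kernel (via FFT)."""
    return np.fft.irfft(np.fft.rfft(profiles, axis=-1) * np.fft.rfft(kernel),
                        n=kernel.size, axis=-1)


def sensorimotor_smear(profile: np.ndarray, epsilon: float,
                       polar_grid: np.ndarray) -> np.ndarray:
    """Smear a response profile circularly with a wrapped Gaussian of SD ε.

    Total mass is preserved; with ε far below the grid spacing the kernel
    collapses to a delta and the profile passes through unchanged.
    """
    kernel = gaussian_kernel(epsilon, polar_grid)
    out = _circulant_smear(np.asarray(profile, dtype=float), kernel)
    return np.maximum(out, 0.0)  # clip FFT round-off


def to_pmv(profile: np.ndarray, polar_grid: np.ndarray) -> PMV:
    """Normalize a non-negative response profile to a probability mass vector."""
    prof = np.asarray(profile, dtype=float)
    if np.any(prof < 0):
        raise ValueError("response profile must be non-negative")
    total = prof.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return PMV(np.asarray(polar_grid, dtype=float), prof / total)


def _circular_interp(x_new: np.ndarray, x: np.ndarray, y: np.ndarray,
                     period: float = 360.0) -> np.ndarray:
    """Linear interpolation of columns of y over a circular x axis."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    x_ext = np.concatenate([xs - period, xs, xs + period])
    y_ext = np.concatenate([ys, ys, ys], axis=0)
    out = np.empty((x_new.size, y.shape[1]))
    for b in range(y.shape[1]):
        out[:, b] = np.interp(x_new, x_ext, y_ext[:, b])
    return out


def regrid_plane(plane: PlaneTemplates,
                 polar_grid: np.ndarray = DEFAULT_POLAR_GRID) -> PlaneTemplates:
    """Interpolate templates (linear per band, circular in θ) onto a new grid."""
    grid = np.asarray(polar_grid, dtype=float)
    if plane.polar.size == grid.size and np.allclose(plane.polar, grid):
        return plane
    return PlaneTemplates(
        plane.lateral, grid,
        _circular_interp(grid, plane.polar, plane.left),
        _circular_interp(grid, plane.polar, plane.right))


class PmvPredictor:
    """Precomputes weighted distances for a plane so PMVs are cheap in {Γ,S,ε}.

    The distance stage is independent of the model parameters, so fitting can
    reuse the (targets × template-angles) distance matrices and only repeat
    the sigmoid / binaural / smear stages per candidate parameter set.

    Targets are the listener's own DTF directions on the response grid
    (virtual-source paradigm with a flat-spectrum stimulus), so the target
    cue at polar angle θ equals the template cue at θ.
    """

    def __init__(self, templates: TemplateSet, scheme,
                 lateral_plane: float = 0.0,
                 polar_grid: np.ndarray = DEFAULT_POLAR_GRID,
                 phi_scale: float = BINAURAL_PHI_SCALE_DEG):
        plane = regrid_plane(templates.plane(lateral_plane), polar_grid)
        self.polar_grid = np.asarray(polar_grid, dtype=float)
        self.lateral = plane.lateral
        self.phi_scale = phi_scale
        w = _resolve_weights(scheme, plane.left.shape[1])
        # D[e][i, j]: distance between target at grid angle i and template at j
        self._d = {}
        for ear, tpl in (("left", plane.left), ("right", plane.right)):
            diff = np.abs(tpl[None, :, :] - tpl[:, None, :])
            self._d[ear] = np.tensordot(diff, w, axes=(2, 0))

    def pmv_matrix(self, params: ModelParams) -> np.ndarray:
        """(n_targets, n_bins) PMVs for every grid target at once."""
        sl = similarity(self._d["left"], params.gamma, params.s)
        sr = similarity(self._d["right"], params.gamma, params.s)
        comb = binaural_combine(sl, sr, self.lateral, self.phi_scale)
        kernel = gaussian_kernel(params.epsilon, self.polar_grid)
        smeared = np.maximum(_circulant_smear(comb, kernel), 0.0)
        total = smeared.sum(axis=1, keepdims=True)
        # extreme {Γ, S} can underflow the similarity to exactly zero for a
        # whole profile; the informationless limit is a uniform response
        dead = (total <= 1e-30).ravel()
        if dead.any():
            smeared[dead] = 1.0
            total = smeared.sum(axis=1, keepdims=True)
        return smeared / total

    def pmv_for_target(self, target_polar: float, params: ModelParams) -> PMV:
        idx = nearest_bin(target_polar, self.polar_grid)
        return PMV(self.polar_grid, self.pmv_matrix(params)[idx])


def nearest_bin(polar_deg: float, polar_grid: np.ndarray) -> int:
    """Nearest grid bin by circular distance; ties go to the lower bin."""
    grid = np.asarray(polar_grid, dtype=float)
    delta = np.abs((grid - polar_deg + 180.0) % 360.0 - 180.0)
    return int(np.argmin(np.round(delta, 9)))  # argmin takes first == lower bin


def predict_pmv(templates: TemplateSet, target_direction, params: ModelParams,
                scheme, polar_grid: np.ndarray = DEFAULT_POLAR_GRID,
                phi_scale: float = BINAURAL_PHI_SCALE_DEG) -> PMV:
    """Full forward pass for one target (lateral, polar) direction."""
    lateral, polar = target_direction
    pred = PmvPredictor(templates, scheme, lateral_plane=lateral,
                        polar_grid=polar_grid, phi_scale=phi_scale)
    return pred.pmv_for_target(polar, params)
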