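"""Parametric synthetic listeners and simulated localization responses.

The generator emulates the acoustic structure the analysis relies on: smooth
directional transfer function (DTF) magnitude spectra with a main spectral
notch whose centre frequency rises monotonically with polar angle over the
front, a secondary notch and a broad peak, rear spectra mirrored with an
octave offset (controllable front–back similarity), lateral-angle-dependent
ear asymmetry, and per-direction spectral jitter.  Responses are drawn from
the model's own PMVs under a known weighting scheme and known {Γ, S, ε}, so
fitting and selection can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .peripheral import ErbBandGrid, erb_band_centers, psg
from .model import (DEFAULT_POLAR_GRID, ModelParams, PlaneTemplates, PmvPredictor,
                    TemplateSet)

__all__ = [
    "SyntheticListenerSpec",
    "DtfSet",
    "ResponseRecord",
    "CohortConfig",
    "Cohort",
    "make_dtf_set",
    "simulate_responses",
    "make_cohort",
    "listener_from_ledger_row",
]

#: Default group-average sensorimotor scatter (deg) used when simulating.
DEFAULT_TRUE_PARAMS = ModelParams(gamma=6.0, s=0.7, epsilon=12.79)


@dataclass(frozen=True)
class SyntheticListenerSpec:
    """Acoustic recipe for one synthetic listener.

    The main notch sits at ``notch_start_freq`` for a source at θ = −30° and
    climbs ``notch_octaves_per_90deg`` octaves per 90° of polar angle over the
    frontal range θ ∈ [−90°, 90°].  Rear directions mirror the frontal
    trajectory shifted by ``rear_offset_octaves`` so front and back are
    spectrally similar but not identical.
    """

    notch_start_freq: float = 6000.0       # Hz, main-notch centre at θ = −30°
    notch_octaves_per_90deg: float = 0.75  # trajectory slope
    notch_depth: float = -25.0             # dB (negative)
    notch_width: float = 0.3               # octaves (Gaussian SD in log2 f)
    peak_freq: float = 4000.0              # Hz, broad pinna peak
    peak_gain: float = 6.0                 # dB
    ear_asymmetry: float = 2.0             # dB of lateral-dependent tilt
    spectral_jitter_sd: float = 2.0        # dB of smooth directional ripple
    rear_offset_octaves: float = 0.3       # front-back trajectory offset
    rng_seed: int = 0

    def __post_init__(self):
        if self.notch_depth >= 0:
            raise ValueError("notch depth must be negative (a notch)")
        if self.notch_width <= 0:
            raise ValueError("notch width must be positive")

    def notch_frequency(self, polar_deg) -> np.ndarray:
        """Main-notch centre frequency (Hz) at polar angle(s) θ ∈ [−90, 270)."""
        theta = np.asarray(polar_deg, dtype=float)
        front = (theta <= 90.0)
        eff = np.where(front, theta, 180.0 - theta)   # mirror rear onto front
        octs = self.notch_octaves_per_90deg * (eff + 30.0) / 90.0
        octs = octs + np.where(front, 0.0, self.rear_offset_octaves)
        return self.notch_start_freq * 2.0 ** octs


@dataclass
class DtfSet:
    """Raw synthetic DTF magnitudes on a common frequency axis."""

    frequencies: np.ndarray                      # (F,), Hz
    sample_rate: float
    planes: dict = field(default_factory=dict)   # lat -> (polar, mag[K, 2, F] linear)
    subject_id: str = "synthetic"


def _gauss_log2(f: np.ndarray, center: float, width_oct: float) -> np.ndarray:
    return np.exp(-0.5 * (np.log2(f / center) / width_oct) ** 2)


def _jitter_field(f: np.ndarray, polar_grid: np.ndarray, sd_db: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth random dB field over (polar angle × frequency).

    Random cosine features, band-limited to ≲1.5 cycles/octave in
    log2-frequency and ≤ 18 harmonics around the polar circle, so spectra
    ripple idiosyncratically per direction yet vary smoothly (correlation
    scale ≈ 20° in θ) — the directional fine structure real pinnae produce.
    Returns shape (len(polar_grid), len(f)).
    """
    if sd_db <= 0:
        return np.zeros((polar_grid.size, f.size))
    x = np.log2(f / f[0])                      # octaves
    th = polar_grid / 360.0                    # circular coordinate
    n_comp = 24
    amps = rng.standard_normal(n_comp) * sd_db * np.sqrt(2.0 / n_comp)
    u = rng.uniform(0.2, 1.5, n_comp)          # cycles per octave
    m = rng.integers(0, 19, n_comp)            # polar harmonics
    phase = rng.uniform(0, 2 * np.pi, n_comp)
    arg = (2 * np.pi * (u[:, None, None] * x[None, None, :]
                        + m[:, None, None] * th[None, :, None])
           + phase[:, None, None])
    return (amps[:, None, None] * np.cos(arg)).sum(axis=0)


def _band_average_matrix(f: np.ndarray, grid: ErbBandGrid) -> np.ndarray:
    """(Nb, F) row-stochastic matrix averaging power within each band window."""
    edges = grid.band_edges()
    if edges[0, 0] < f[0] - 1e-9 or edges[-1, 1] > f[-1] + 1e-9:
        raise ValueError("frequency axis does not cover the band windows")
    m = np.zeros((grid.n_bands, f.size))
    for b, (lo, hi) in enumerate(edges):
        sel = (f >= lo) & (f <= hi)
        m[b, sel] = 1.0 / sel.sum()
    return m


def make_dtf_set(spec: SyntheticListenerSpec = SyntheticListenerSpec(),
                 polar_grid: np.ndarray = DEFAULT_POLAR_GRID,
                 lateral_planes=(0.0,),
                 grid: ErbBandGrid | None = None,
                 sample_rate: float = 48000.0,
                 n_fft: int = 2048,
                 subject_id: str = "synthetic") -> tuple[TemplateSet, DtfSet]:
    """Generate a synthetic listener: PSG templates plus the raw DTF spectra.

    Deterministic given ``spec.rng_seed``.  Raises if the notch trajectory
    would leave the 700 Hz – 18 kHz band range anywhere on the polar grid.
    """
    if grid is None:
        grid = erb_band_centers()
    polar_grid = np.asarray(polar_grid, dtype=float)
    traj = spec.notch_frequency(polar_grid)
    if traj.min() < 700.0 or traj.max() > 18000.0:
        raise ValueError(
            f"notch trajectory [{traj.min():.0f}, {traj.max():.0f}] Hz leaves "
            "the 700-18000 Hz band range; adjust the listener spec")
    rng = np.random.default_rng(spec.rng_seed)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    f = np.maximum(freqs, freqs[1])          # avoid log(0) at DC
    bandmat = _band_average_matrix(freqs, grid)
    tilt = np.log2(f / 3000.0) / 2.0

    dtfs = DtfSet(freqs, sample_rate, subject_id=subject_id)
    planes: dict[float, PlaneTemplates] = {}
    for lat in lateral_planes:
        mags = np.empty((polar_grid.size, 2, freqs.size))
        gradients = {"left": [], "right": []}
        lat_factor = np.sin(np.deg2rad(lat))
        ripple = {ear: _jitter_field(f, polar_grid, spec.spectral_jitter_sd, rng)
                  for ear in ("left", "right")}
        for i, theta in enumerate(polar_grid):
            f_notch = traj[i]
            base = (spec.peak_gain * _gauss_log2(f, spec.peak_freq, 0.8)
                    + spec.notch_depth * _gauss_log2(f, f_notch, spec.notch_width)
                    + 0.4 * spec.notch_depth
                    * _gauss_log2(f, f_notch * 1.8, spec.notch_width))
            for e, (ear, sign) in enumerate((("left", +1.0), ("right", -1.0))):
                db = (base + sign * lat_factor * spec.ear_asymmetry * tilt
                      + ripple[ear][i])
                mags[i, e] = 10.0 ** (db / 20.0)
                xi = 10.0 * np.log10(bandmat @ mags[i, e] ** 2)
                gradients[ear].append(psg(xi).xi_tilde)
        dtfs.planes[float(lat)] = (polar_grid.copy(), mags)
        planes[float(lat)] = PlaneTemplates(
            float(lat), polar_grid.copy(),
            np.asarray(gradients["left"]), np.asarray(gradients["right"]))

    return TemplateSet(subject_id, grid, planes), dtfs


RESPONSE_COLUMNS = ("subject_id", "target_lat", "target_pol",
                    "response_lat", "response_pol")


@dataclass(frozen=True)
class ResponseRecord:
    """One localization trial: target and response in lateral/polar degrees."""

    subject_id: str
    target_lat: float
    target_pol: float
    response_lat: float
    response_pol: float

    def __post_init__(self):
        for v in (self.target_pol, self.response_pol):
            if not (-90.0 <= v < 270.0):
                raise ValueError("polar angles must lie in [-90, 270)")
        for v in (self.target_lat, self.response_lat):
            if not (-90.0 <= v <= 90.0):
                raise ValueError("lateral angles must lie in [-90, 90]")


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=RESPONSE_COLUMNS)


def simulate_responses(templates: TemplateSet, scheme,
                       params: ModelParams = DEFAULT_TRUE_PARAMS,
                       targets=None, n_per_target: int = 10, seed: int = 0,
                       polar_grid: np.ndarray = DEFAULT_POLAR_GRID) -> pd.DataFrame:
    """Draw responses i.i.d. from the model's PMV at each target.

    ``targets`` is a sequence of (lateral, polar) pairs; by default every bin
    of the response grid on the median plane.  Returns a response table with
    columns ``subject_id, target_lat, target_pol, response_lat, response_pol``.
    """
    rng = np.random.default_rng(seed)
    if targets is None:
        targets = [(0.0, th) for th in polar_grid]
    frame_targets = pd.DataFrame(targets, columns=["lat", "pol"])
    rows = []
    for lat, group in frame_targets.groupby("lat", sort=True):
        pred = PmvPredictor(templates, scheme, lateral_plane=float(lat),
                            polar_grid=polar_grid)
        for pol in group["pol"]:
            pmv = pred.pmv_for_target(float(pol), params)
            draws = rng.choice(pmv.polar, size=n_per_target, p=pmv.p)
            for r in draws:
                rows.append((templates.subject_id, float(lat), float(pol),
                             float(lat), float(r)))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a cohort of independent synthetic listeners.

    ``true_scheme`` / ``true_params`` may be a single value applied to every
    subject or a per-subject sequence.  Each subject's acoustic spec is
    jittered around the defaults so listeners differ, and all randomness flows
    through one seed.
    """

    n_subjects: int = 17
    true_scheme: object = "NR"                  # name, scheme, or per-subject list
    true_params: object = DEFAULT_TRUE_PARAMS   # ModelParams or per-subject list
    targets_per_plane: int = 24
    n_trials: int = 300                         # per subject, per plane
    lateral_planes: tuple = (0.0,)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials < 1 or self.targets_per_plane < 1:
            raise ValueError("cohort sizes must be positive")


@dataclass
class Cohort:
    """Synthetic cohort: templates, DTFs and responses per subject + ground truth."""

    templates: dict                      # subject_id -> TemplateSet
    dtfs: dict                           # subject_id -> DtfSet
    responses: pd.DataFrame              # pooled response table
    ground_truth: pd.DataFrame           # per-subject scheme + params ledger
    config: CohortConfig

    @property
    def subject_ids(self) -> list[str]:
        return list(self.templates)


def listener_from_ledger_row(row, polar_grid: np.ndarray = DEFAULT_POLAR_GRID,
                             lateral_planes=(0.0,),
                             grid: ErbBandGrid | None = None) -> TemplateSet:
    """Rebuild a cohort subject's templates from its ground-truth ledger row."""
    import dataclasses

    names = {f.name for f in dataclasses.fields(SyntheticListenerSpec)}
    spec = SyntheticListenerSpec(**{k: (int(row[k]) if k == "rng_seed"
                                        else float(row[k]))
                                    for k in names})
    tset, _ = make_dtf_set(spec, polar_grid=polar_grid,
                           lateral_planes=lateral_planes, grid=grid,
                           subject_id=str(row["subject_id"]))
    return tset


def _per_subject(value, i, n):
    if isinstance(value, (list, tuple)) and len(value) == n:
        return value[i]
    return value


def _cohort_targets(config: CohortConfig, polar_grid: np.ndarray):
    step = max(1, polar_grid.size // config.targets_per_plane)
    sel = polar_grid[::step][:config.targets_per_plane]
    per = np.full(sel.size, config.n_trials // sel.size)
    per[: config.n_trials % sel.size] += 1
    return sel, per


def make_cohort(config: CohortConfig = CohortConfig(),
                polar_grid: np.ndarray = DEFAULT_POLAR_GRID,
                grid: ErbBandGrid | None = None) -> Cohort:
    """Generate a cohort of synthetic listeners with simulated responses."""
    from . import schemes as _schemes  # local import: schemes builds on model

    if grid is None:
        grid = erb_band_centers()
    master = np.random.default_rng(config.seed)
    base = SyntheticListenerSpec()
    targets_pol, trials_per_target = _cohort_targets(config, polar_grid)

    templates, dtfs, resp_frames, truth_rows = {}, {}, [], []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        sub_seed = int(master.integers(0, 2**31 - 1))
        jit = np.random.default_rng(sub_seed)
        spec = replace(
            base,
            notch_start_freq=float(base.notch_start_freq * 2.0 ** jit.normal(0, 0.1)),
            notch_octaves_per_90deg=float(np.clip(
                base.notch_octaves_per_90deg + jit.normal(0, 0.05), 0.5, 0.95)),
            notch_depth=float(base.notch_depth + jit.normal(0, 2.0)),
            peak_freq=float(base.peak_freq * 2.0 ** jit.normal(0, 0.1)),
            rear_offset_octaves=float(np.clip(
                base.rear_offset_octaves + jit.normal(0, 0.05), 0.1, 0.6)),
            rng_seed=sub_seed)
        tset, dset = make_dtf_set(spec, polar_grid=polar_grid,
                                  lateral_planes=config.lateral_planes,
                                  grid=grid, subject_id=sid)
        templates[sid] = tset
        dtfs[sid] = dset

        scheme_spec = _per_subject(config.true_scheme, i, config.n_subjects)
        if isinstance(scheme_spec, str):
            scheme = _schemes.make_scheme(scheme_spec, grid, templates=tset)
            scheme_name = scheme.name
        else:
            scheme, scheme_name = scheme_spec, scheme_spec.name
        params = _per_subject(config.true_params, i, config.n_subjects)

        for lat in config.lateral_planes:
            tgts = [(float(lat), float(p)) for p in targets_pol]
            parts = []
            for (tgt, n_rep) in zip(tgts, trials_per_target):
                if n_rep == 0:
                    continue
                parts.append(simulate_responses(
                    tset, scheme, params, targets=[tgt], n_per_target=int(n_rep),
                    seed=int(jit.integers(0, 2**31 - 1)), polar_grid=polar_grid))
            resp_frames.extend(parts)

        # full acoustic spec in the ledger so the listener is reconstructible
        truth_rows.append({"subject_id": sid, "scheme": scheme_name,
                           "gamma": params.gamma, "s": params.s,
                           "epsilon": params.epsilon, **asdict(spec)})

    return Cohort(templates, dtfs,
                  pd.concat(resp_frames, ignore_index=True),
                  pd.DataFrame(truth_rows), config)
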