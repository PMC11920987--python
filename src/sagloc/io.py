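"""Standard-format I/O: SOFA HRTF containers, response tables, coordinates, config.

SOFA (Spatially Oriented Format for Acoustics) files are HDF5 containers;
reading and writing of the SimpleFreeFieldHRIR convention is done directly
with h5py, covering the data and metadata the pipeline needs.  Directions are
converted between SOFA spherical coordinates (azimuth/elevation) and the
interaural-polar system (lateral ϕ, polar θ) the model operates in; the
lateral sign convention is positive ϕ = left.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .peripheral import ErbBandGrid, erb_band_centers
from .synthetic import DtfSet, RESPONSE_COLUMNS

__all__ = [
    "sph_to_interaural",
    "interaural_to_sph",
    "HrtfSet",
    "read_sofa_hrtf",
    "write_sofa_hrtf",
    "write_dtf_sofa",
    "hrtf_spectra",
    "dtf_from_hrtf",
    "minimum_phase_ir",
    "read_responses",
    "write_responses",
    "write_spectral_table",
    "read_spectral_table",
    "RunConfig",
    "config_hash",
]


# --------------------------------------------------------------------------
# coordinates

def sph_to_interaural(azimuth_deg, elevation_deg):
    """SOFA spherical (azi CCW from front, ele) → interaural-polar (ϕ, θ).

    ϕ = asin(sin azi · cos ele) ∈ [−90°, 90°], positive left;
    θ = atan2(sin ele, cos azi · cos ele) mapped to [−90°, 270°).
    """
    azi = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    ele = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    lat = np.rad2deg(np.arcsin(np.clip(np.sin(azi) * np.cos(ele), -1.0, 1.0)))
    pol = np.rad2deg(np.arctan2(np.sin(ele), np.cos(azi) * np.cos(ele)))
    pol = np.where(pol < -90.0, pol + 360.0, pol)
    # the seam at -90/270 is ill-conditioned; snap rounding spill-over back
    pol = np.where(pol >= 270.0 - 1e-6, pol - 360.0, pol)
    return lat, pol


def interaural_to_sph(lateral_deg, polar_deg):
    """Interaural-polar (ϕ, θ) → SOFA spherical (azimuth ∈ [0, 360), elevation)."""
    lat = np.deg2rad(np.asarray(lateral_deg, dtype=float))
    pol = np.deg2rad(np.asarray(polar_deg, dtype=float))
    y = np.sin(lat)
    x = np.cos(lat) * np.cos(pol)
    z = np.cos(lat) * np.sin(pol)
    azi = np.rad2deg(np.arctan2(y, x)) % 360.0
    ele = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    return azi, ele


# --------------------------------------------------------------------------
# SOFA

@dataclass
class HrtfSet:
    """Raw HRTF/DTF data: impulse responses with source positions."""

    ir: np.ndarray                # (M, 2, N): directions × ears (L, R) × taps
    sample_rate: float
    source_azimuth: np.ndarray    # (M,) degrees
    source_elevation: np.ndarray  # (M,) degrees

    @property
    def lateral_polar(self):
        """Source directions in interaural-polar coordinates (ϕ, θ)."""
        return sph_to_interaural(self.source_azimuth, self.source_elevation)


def read_sofa_hrtf(path) -> HrtfSet:
    """Read a SimpleFreeFieldHRIR SOFA file (HDF5 level)."""
    with h5py.File(path, "r") as f:
        conv = f.attrs.get("SOFAConventions", b"")
        conv = conv.decode() if isinstance(conv, bytes) else str(conv)
        if conv != "SimpleFreeFieldHRIR":
            raise ValueError(
                f"unsupported SOFA convention {conv!r}; expected SimpleFreeFieldHRIR")
        ir = np.asarray(f["Data.IR"])
        fs = float(np.asarray(f["Data.SamplingRate"]).ravel()[0])
        pos = np.asarray(f["SourcePosition"])
    if ir.ndim != 3 or ir.shape[1] != 2:
        raise ValueError("expected Data.IR of shape (M, 2, N) for two ears")
    return HrtfSet(ir, fs, pos[:, 0].astype(float), pos[:, 1].astype(float))


def write_sofa_hrtf(path, ir: np.ndarray, sample_rate: float,
                    source_azimuth, source_elevation) -> None:
    """Write a minimal SimpleFreeFieldHRIR SOFA (HDF5) file."""
    ir = np.asarray(ir, dtype=float)
    m = ir.shape[0]
    pos = np.column_stack([np.asarray(source_azimuth, float),
                           np.asarray(source_elevation, float),
                           np.full(m, 1.2)])
    with h5py.File(path, "w") as f:
        f.attrs["Conventions"] = "SOFA"
        f.attrs["Version"] = "2.1"
        f.attrs["SOFAConventions"] = "SimpleFreeFieldHRIR"
        f.attrs["SOFAConventionsVersion"] = "1.0"
        f.attrs["DataType"] = "FIR"
        f.attrs["RoomType"] = "free field"
        f.create_dataset("Data.IR", data=ir)
        f.create_dataset("Data.SamplingRate", data=np.array([sample_rate]))
        f["Data.SamplingRate"].attrs["Units"] = "hertz"
        f.create_dataset("Data.Delay", data=np.zeros((1, ir.shape[1])))
        sp = f.create_dataset("SourcePosition", data=pos)
        sp.attrs["Type"] = "spherical"
        sp.attrs["Units"] = "degree, degree, metre"
        f.create_dataset("ListenerPosition", data=np.zeros((1, 3)))
        f.create_dataset("ReceiverPosition", data=np.zeros((ir.shape[1], 3, 1)))
        f.create_dataset("EmitterPosition", data=np.zeros((1, 3, 1)))


def minimum_phase_ir(magnitude: np.ndarray, n_fft: int) -> np.ndarray:
    """Minimum-phase impulse response from a one-sided magnitude spectrum.

    Homomorphic construction: fold the real cepstrum of log|H| and
    exponentiate.  The magnitude of the result matches |H| to numerical
    precision.
    """
    mag = np.maximum(np.asarray(magnitude, dtype=float), 1e-12)
    log_mag = np.log(mag)
    cep = np.fft.irfft(log_mag, n=n_fft)
    fold = cep.copy()
    fold[1:(n_fft + 1) // 2] *= 2.0
    fold[(n_fft // 2) + 1:] = 0.0
    return np.fft.irfft(np.exp(np.fft.rfft(fold, n=n_fft)), n=n_fft)


def write_dtf_sofa(dtfs: DtfSet, path) -> None:
    """Write a synthetic DTF set as SOFA, via minimum-phase impulse responses."""
    n_fft = 2 * (dtfs.frequencies.size - 1)
    irs, azis, eles = [], [], []
    for lat, (polar, mags) in sorted(dtfs.planes.items()):
        for i, pol in enumerate(polar):
            azi, ele = interaural_to_sph(lat, pol)
            azis.append(float(azi))
            eles.append(float(ele))
            irs.append([minimum_phase_ir(mags[i, e], n_fft) for e in (0, 1)])
    write_sofa_hrtf(path, np.asarray(irs), dtfs.sample_rate,
                    np.asarray(azis), np.asarray(eles))


def hrtf_spectra(hrtf: HrtfSet, n_fft: int | None = None):
    """Magnitude spectra of an HRTF set: (frequencies, |H| of shape (M, 2, F))."""
    n = n_fft or hrtf.ir.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / hrtf.sample_rate)
    return freqs, np.abs(np.fft.rfft(hrtf.ir, n=n, axis=-1))


def dtf_from_hrtf(magnitudes: np.ndarray) -> np.ndarray:
    """Remove direction-independent spectral characteristics per ear.

    Subtracts the across-direction mean log-magnitude from every direction's
    log-magnitude spectrum (input and output are linear magnitudes of shape
    (M, ears, F)); a filter common to all directions therefore cancels.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.ndim != 3 or mags.shape[0] < 2:
        raise ValueError("need (directions, ears, freqs) with >= 2 directions")
    log_mag = np.log(np.maximum(mags, 1e-12))
    return np.exp(log_mag - log_mag.mean(axis=0, keepdims=True))


# --------------------------------------------------------------------------
# tables

def write_responses(responses: pd.DataFrame, path) -> None:
    """Response table CSV: subject_id, target/response lateral & polar (deg)."""
    responses.loc[:, list(RESPONSE_COLUMNS)].to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    return df


def write_spectral_table(dtfs: DtfSet, path) -> None:
    """Plain long-format spectral table: lat, pol, ear, freq_hz, magnitude_db."""
    rows = []
    for lat, (polar, mags) in sorted(dtfs.planes.items()):
        for i, pol in enumerate(polar):
            for e, ear in enumerate(("left", "right")):
                db = 20.0 * np.log10(np.maximum(mags[i, e], 1e-12))
                rows.append(pd.DataFrame({
                    "lat": lat, "pol": pol, "ear": ear,
                    "freq_hz": dtfs.frequencies, "magnitude_db": db}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_spectral_table(path, sample_rate: float = 48000.0) -> DtfSet:
    df = pd.read_csv(path)
    freqs = np.sort(df["freq_hz"].unique())
    out = DtfSet(freqs, sample_rate)
    for lat, grp in df.groupby("lat"):
        polars = np.sort(grp["pol"].unique())
        mags = np.empty((polars.size, 2, freqs.size))
        for i, pol in enumerate(polars):
            for e, ear in enumerate(("left", "right")):
                sub = grp[(grp["pol"] == pol) & (grp["ear"] == ear)]
                sub = sub.sort_values("freq_hz")
                mags[i, e] = 10.0 ** (sub["magnitude_db"].to_numpy() / 20.0)
        out.planes[float(lat)] = (polars.astype(float), mags)
    return out


# --------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """All tunable constants of a pipeline run, serializable to YAML/JSON."""

    band_low_hz: float = 700.0
    band_high_hz: float = 18000.0
    band_step_erb: float = 1.0
    nr_center_hz: float = 8000.0
    dt_center_hz: float = 6000.0
    bump_width_octaves: float = 1.0
    bump_floor: float = 0.05
    lp_decay_per_octave: float = 0.5
    binaural_phi_scale_deg: float = 13.0
    polar_bin_deg: float = 5.0
    pmv_floor: float = 1e-9
    gamma_bounds: tuple = (0.1, 100.0)
    s_bounds: tuple = (-20.0, 20.0)
    epsilon_bounds: tuple = (3.0, 50.0)
    boundary_tol: float = 0.01
    lateral_fit_range: tuple = (-10.0, 10.0)
    lateral_planes: tuple = (0.0,)
    selection_mode: str = "standard"
    rfx_samples: int = 1_000_000
    seed: int = 0

    def band_grid(self) -> ErbBandGrid:
        return erb_band_centers(self.band_low_hz, self.band_high_hz,
                                self.band_step_erb)

    def polar_grid(self) -> np.ndarray:
        return np.arange(-90.0, 270.0, self.polar_bin_deg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_jsonable(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("gamma_bounds", "s_bounds", "epsilon_bounds",
                    "lateral_fit_range", "lateral_planes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def config_hash(config: RunConfig) -> str:
    """Stable hash of the semantic configuration fields."""
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
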