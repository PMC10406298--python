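"""Parametric single-voxel fMRI noise.

Real fMRI noise mixes slow scanner drift, temporally autocorrelated
(AR) machine noise, quasi-periodic physiological fluctuations (cardiac
and respiratory cycles, aliased by the slow TR sampling) and thermal
white noise.  This module generates each component parametrically and
combines the sum with a simulated signal at a target SNR, defined as
sd(signal) / sd(noise).  Externally estimated parameters (e.g. from a
noise-fitting tool run on real resting-state data) can be imported from
a YAML file.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sp_signal

__all__ = [
    "NoiseModel",
    "generate_noise",
    "combine_signal_noise",
    "import_noise_parameters",
    "export_noise_parameters",
]

#: Samples discarded to let the AR process reach stationarity.
AR_BURN_IN = 100


class NoiseParameterError(ValueError):
    """An invalid or unknown noise-model parameter."""


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of the additive single-voxel noise model.

    Component magnitudes are standard deviations in the same arbitrary
    units; only their ratios matter because the summed noise is rescaled
    against the signal to hit ``snr``.  ``physio`` lists (frequency Hz,
    amplitude) sinusoids; frequencies above the TR Nyquist are aliased
    onto the sampled grid rather than dropped.  Defaults give an evenly
    mixed noise floor with moderate autocorrelation, the regime in which
    optimality landscapes degrade visibly but keep their structure.
    """

    drift_amplitude: float = 1.0
    drift_period: float = 128.0
    ar_rho: float = 0.4
    ar_sigma: float = 1.0
    physio: tuple[tuple[float, float], ...] = ((0.2, 0.5), (1.17, 0.5))
    white_sigma: float = 1.0
    snr: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not abs(self.ar_rho) < 1:
            raise NoiseParameterError(
                f"ar_rho must satisfy |rho| < 1 (stationarity), got {self.ar_rho}"
            )
        for name in ("drift_amplitude", "drift_period", "ar_sigma", "white_sigma"):
            if getattr(self, name) < 0:
                raise NoiseParameterError(f"{name} must be >= 0")
        for freq, amp in self.physio:
            if freq <= 0 or amp < 0:
                raise NoiseParameterError(
                    f"physio entries need frequency > 0 and amplitude >= 0, "
                    f"got ({freq}, {amp})"
                )
        if self.snr <= 0:
            raise NoiseParameterError(f"snr must be > 0, got {self.snr}")


def _alias_frequency(freq: float, fs: float) -> float:
    """Fold ``freq`` into the baseband [0, fs/2] of sampling rate fs."""
    f = freq % fs
    return fs - f if f > fs / 2 else f


def _drift(model: NoiseModel, n: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency drift from a random-coefficient cosine basis.

    Uses the discrete cosine set with frequencies k / (2 n tr) up to the
    cutoff 1/drift_period, normalized to sd = drift_amplitude.
    """
    if model.drift_amplitude == 0 or model.drift_period <= 0:
        return np.zeros(n)
    n_basis = int(np.floor(2 * n * tr / model.drift_period))
    if n_basis < 1:
        return np.zeros(n)
    t = np.arange(n)
    basis = np.stack(
        [np.cos(np.pi * k * (t + 0.5) / n) for k in range(1, n_basis + 1)], axis=1
    )
    d = basis @ rng.standard_normal(n_basis)
    sd = d.std()
    if sd == 0:
        return np.zeros(n)
    return model.drift_amplitude * d / sd


def _autoregressive(
    model: NoiseModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) with sd = ar_sigma, burned in for AR_BURN_IN samples."""
    if model.ar_sigma == 0:
        return np.zeros(n)
    innov_sd = model.ar_sigma * np.sqrt(1 - model.ar_rho**2)
    e = rng.standard_normal(n + AR_BURN_IN) * innov_sd
    series = sp_signal.lfilter([1.0], [1.0, -model.ar_rho], e)
    return series[AR_BURN_IN:]

def _physiological(
    model: NoiseModel, n: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase sinusoids at TR-aliased physiological frequencies."""
    t = np.arange(n) * tr
    out = np.zeros(n)
    fs = 1.0 / tr
    for freq, amp in model.physio:
        phase = rng.uniform(0, 2 * np.pi)
        if amp == 0:
            continue
        f_obs = _alias_frequency(freq, fs)
        out += amp * np.sin(2 * np.pi * f_obs * t + phase)
    return out


def generate_noise(
    model: NoiseModel,
    n_scans: int,
    tr: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sum of independently generated drift, AR, physiological and white
    components for one voxel time series."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    drift = _drift(model, n_scans, tr, rng)
    ar = _autoregressive(model, n_scans, rng)
    physio = _physiological(model, n_scans, tr, rng)
    white = rng.standard_normal(n_scans) * model.white_sigma
    return drift + ar + physio + white


def combine_signal_noise(
    y: np.ndarray, noise: np.ndarray, snr: float, reference_sd: float | None = None
) -> tuple[np.ndarray, float]:
    """Add noise to a signal at a target sd(signal)/sd(noise) ratio.

    By default the reference is the signal's own standard deviation, so
    the combined series has exactly sd(signal)/sd(noise) = snr.  Passing
    ``reference_sd`` fixes the noise level in absolute response units
    instead (sd(noise) = reference_sd / snr): a whole family of designs
    then receives statistically identical noise, the way a single
    measured noise template would be reused across simulations, rather
    than noise tailored to each design's signal variance.

    Returns the combined series and the scale factor applied to the
    noise (provenance).  A zero-variance signal cannot define a relative
    SNR: the noise is then added unscaled, with a warning.  ``snr = inf``
    or an all-zero noise vector returns the signal unchanged.
    """
    y = np.asarray(y, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if len(y) != len(noise):
        raise ValueError(f"length mismatch: signal {len(y)} vs noise {len(noise)}")
    sd_noise = noise.std()
    if np.isinf(snr) or sd_noise == 0:
        return y.copy(), 0.0
    sd_ref = y.std() if reference_sd is None else float(reference_sd)
    if sd_ref == 0:
        warnings.warn(
            "signal has zero variance; SNR is undefined, adding noise unscaled"
        )
        return y + noise, 1.0
    scale = sd_ref / (snr * sd_noise)
    return y + scale * noise, scale


def export_noise_parameters(model: NoiseModel, path: str | Path) -> None:
    """Write a noise model to YAML (inverse of import_noise_parameters)."""
    data = asdict(model)
    data["physio"] = [list(pair) for pair in model.physio]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def import_noise_parameters(path: str | Path) -> NoiseModel:
    """Load and validate noise parameters from a YAML mapping.

    The file must contain every NoiseModel field (``seed`` may be
    omitted); unknown fields are rejected by name, so externally
    estimated parameter files fail loudly rather than silently.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise NoiseParameterError(f"{path} does not contain a parameter mapping")
    known = {f.name for f in fields(NoiseModel)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise NoiseParameterError(f"unknown noise parameters: {unknown}")
    missing = sorted(known - set(data) - {"seed"})
    if missing:
        raise NoiseParameterError(f"missing noise parameters: {missing}")
    if "physio" in data:
        try:
            data["physio"] = tuple(
                (float(f), float(a)) for f, a in data["physio"]
            )
        except (TypeError, ValueError) as exc:
            raise NoiseParameterError(
                f"physio must be a list of (frequency, amplitude) pairs: {exc}"
            ) from exc
    return NoiseModel(**data)
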