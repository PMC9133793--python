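"""Synthetic MEG epoch generation with ground-truth deviance effects.

The generator emulates a roving-oddball recording as a low-rank spatiotemporal
model: every trial contains a common auditory evoked component, and deviant
trials (position 1 in a train) additionally contain a deviance-specific
component whose temporal kernel turns on near 100 ms and peaks near 280 ms.
Standards at positions k >= 2 carry an attenuated copy of the deviance
component; the attenuation profile is the experimental variable of interest:

* ``control``  - attenuation deepens with repetition (cumulative accrual of
  "standardness"), so 1sts-vs-4ths is an easier contrast than 1sts-vs-2nds;
* ``dyslexia`` - attenuation is immediate but flat across repetitions, so all
  standard positions are equally distinguishable from deviants;
* ``null``     - no attenuation at all (no condition information anywhere).

Noise is spatially correlated Gaussian noise (ill-conditioned covariance so
multivariate noise normalization is consequential), plus an optional per-train
shared low-frequency drift.  The drift term is what makes tiny same-train
contrasts (e.g. 4ths vs 5ths at a handful of trials) trend below chance under
cross-validation: trials that share a train share the drift, which couples
training and test folds.  With fully independent trials, cross-validated
accuracy would be exactly unbiased at chance.

This model is analytically checkable by projection onto the ground-truth
topographies and is not claimed to be biophysical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GRAD, MAG, EpochsData, SensorLayout, default_layout
from .design import TrainDesign

__all__ = [
    "AttenuationProfile",
    "GroundTruth",
    "ArtifactLog",
    "attenuation_profile",
    "default_times",
    "default_ground_truth",
    "gamma_kernel",
    "simulate_epochs",
    "inject_artifacts",
]

#: spike heights (units per sensor type) used by default when corrupting
#: trials; twice the rejection thresholds, so corrupted trials are always
#: caught by artifact rejection.
DEFAULT_ARTIFACT_AMPLITUDE = {MAG: 20_000.0, GRAD: 5_000.0}


@dataclass(frozen=True)
class AttenuationProfile:
    """Multiplier applied to the deviance component per position-in-train."""

    name: str
    multipliers: Mapping[int, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.multipliers.values()), float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("attenuation multipliers must lie in [0, 1]")
        if self.multipliers.get(1, 1.0) != 1.0:
            raise ValueError("deviants (position 1) must have multiplier 1")

    def __call__(self, position: int) -> float:
        kmax = max(self.multipliers)
        return float(self.multipliers[min(position, kmax)])


_PROFILES = {
    "control": {1: 1.0, 2: 0.6, 3: 0.4, 4: 0.2, 5: 0.12, 6: 0.08},
    "dyslexia": {1: 1.0, 2: 0.4, 3: 0.4, 4: 0.4, 5: 0.4, 6: 0.4},
    "null": {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0, 6: 1.0},
}


def attenuation_profile(name: str) -> AttenuationProfile:
    """Named repetition-attenuation profiles ("control", "dyslexia", "null")."""
    try:
        return AttenuationProfile(name, dict(_PROFILES[name]))
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}") from None


@dataclass
class GroundTruth:
    """Simulator parameters; kept so parameter-recovery tests have known truth."""

    times: np.ndarray  # ms grid the kernels are defined on
    common_topography: np.ndarray  # unit-norm (n_sensors,)
    deviance_topography: np.ndarray  # unit-norm (n_sensors,)
    common_kernel: np.ndarray  # (n_times,), includes its amplitude scale
    deviance_kernel: np.ndarray  # (n_times,), unit peak
    deviance_amplitude: float
    attenuation: AttenuationProfile
    trial_jitter_sd: float
    noise_covariance: np.ndarray  # (n_sensors, n_sensors) SPD, unit average variance
    noise_scale: float
    train_drift_sd: float = 0.0  # per-train shared low-frequency noise

    def __post_init__(self) -> None:
        pre = self.times < 0
        for kern in (self.common_kernel, self.deviance_kernel):
            if np.any(np.abs(np.asarray(kern)[pre]) > 1e-12):
                raise ValueError("kernels must be zero over the prestimulus window")
        cov = np.asarray(self.noise_covariance, float)
        if not np.allclose(cov, cov.T):
            raise ValueError("noise covariance must be symmetric")


def default_times(sfreq: float = 1000.0, tmin_ms: float = -200.0, tmax_ms: float = 550.0) -> np.ndarray:
    """Epoch time grid in ms (default -200..550 at 1,000 Hz: 751 samples)."""
    step = 1000.0 / sfreq
    n = int(round((tmax_ms - tmin_ms) / step)) + 1
    return tmin_ms + step * np.arange(n)


def gamma_kernel(times: np.ndarray, onset_ms: float, peak_ms: float, shape: float = 2.0) -> np.ndarray:
    """Smooth gamma-like bump: zero before onset, unit amplitude at the peak."""
    if peak_ms <= onset_ms:
        raise ValueError("peak must come after onset")
    x = (np.asarray(times, float) - onset_ms) / (peak_ms - onset_ms)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** shape * np.exp(shape * (1.0 - x[pos]))
    return out


def _random_unit(rng: np.random.Generator, p: int) -> np.ndarray:
    v = rng.standard_normal(p)
    return v / np.linalg.norm(v)


def _random_spd(rng: np.random.Generator, p: int, condition: float = 100.0) -> np.ndarray:
    """Random orthogonal mixing of exponentially decaying eigenvalues.

    Scaled to unit average sensor variance (trace = p) so that
    ``noise_scale`` sets the RMS noise amplitude directly.
    """
    q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    lam = np.geomspace(1.0, 1.0 / condition, p)
    lam *= p / lam.sum()
    return (q * lam) @ q.T


def default_ground_truth(
    layout: SensorLayout | None = None,
    times: np.ndarray | None = None,
    profile: str = "control",
    seed: int | None = None,
    *,
    deviance_amplitude: float = 60.0,
    common_amplitude: float = 250.0,
    noise_scale: float = 100.0,
    trial_jitter_sd: float = 0.2,
    train_drift_sd: float = 100.0,
    deviance_onset_ms: float = 100.0,
    deviance_peak_ms: float = 280.0,
    noise_condition: float = 100.0,
) -> GroundTruth:
    """Ground truth with the default component latencies and noise model.

    Amplitudes are in the nominal sensor units (fT-scale); the defaults put
    single-trial peak-to-peak amplitudes far below the artifact-rejection
    thresholds and are calibrated so that a default cohort's deviant-vs-all-
    standards decoding peaks in the 60-80% accuracy band.
    """
    layout = layout if layout is not None else default_layout()
    times = times if times is not None else default_times()
    rng = np.random.default_rng(seed)
    p = layout.n_sensors
    common = _random_unit(rng, p)
    dev = rng.standard_normal(p)
    dev -= common * (common @ dev)  # orthogonal, so projection oracles are clean
    dev /= np.linalg.norm(dev)
    return GroundTruth(
        times=times,
        common_topography=common,
        deviance_topography=dev,
        common_kernel=common_amplitude * gamma_kernel(times, 30.0, 100.0),
        deviance_kernel=gamma_kernel(times, deviance_onset_ms, deviance_peak_ms),
        deviance_amplitude=deviance_amplitude,
        attenuation=attenuation_profile(profile),
        trial_jitter_sd=trial_jitter_sd,
        noise_covariance=_random_spd(rng, p, noise_condition),
        noise_scale=noise_scale,
        train_drift_sd=train_drift_sd,
    )


def simulate_epochs(
    design: TrainDesign,
    truth: GroundTruth,
    layout: SensorLayout | None = None,
    seed: int | None = None,
) -> EpochsData:
    """Render a design into sensor epochs under the ground-truth model.

    Each trial is ``common + m_k * A * (1 + jitter) * deviance + drift +
    correlated noise`` where ``m_k`` is the attenuation multiplier of the
    trial's position-in-train (deviants get 1).  Bitwise deterministic given
    the seed.
    """
    layout = layout if layout is not None else default_layout(truth.common_topography.size)
    if design.n_trials == 0:
        raise ValueError("design has no trials")
    p = layout.n_sensors
    if truth.common_topography.size != p:
        raise ValueError("ground-truth topographies do not match the layout")
    try:
        chol = np.linalg.cholesky(truth.noise_covariance)
    except np.linalg.LinAlgError:
        raise ValueError("noise covariance must be positive definite") from None

    rng = np.random.default_rng(seed)
    times = truth.times
    t = times.size
    n = design.n_trials
    rows = design.trial_rows
    positions = rows["position_in_train"].to_numpy()
    train_idx = rows["train_index"].to_numpy()
    n_trains = int(train_idx.max()) + 1

    common = np.outer(truth.common_topography, truth.common_kernel)  # (p, t)
    dev = np.outer(truth.deviance_topography, truth.deviance_kernel)

    mult = np.array([truth.attenuation(int(k)) for k in positions])
    jitter = rng.normal(0.0, truth.trial_jitter_sd, n) if truth.trial_jitter_sd > 0 else np.zeros(n)
    gains = mult * truth.deviance_amplitude * (1.0 + jitter)  # (n,)

    data = np.empty((n, p, t))
    data[:] = common[None]
    data += gains[:, None, None] * dev[None]

    if truth.train_drift_sd > 0:
        # smooth per-train time courses: random mix of a ramp and a half-sine,
        # shared by every trial in the train (survives filtering and baseline
        # normalization, unlike a DC offset)
        u = rng.standard_normal((n_trains, p))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coeff = rng.standard_normal((n_trains, 2))
        frac = (times - times[0]) / (times[-1] - times[0])
        basis = np.stack([frac - 0.5, np.sin(np.pi * frac)])  # (2, t)
        course = coeff @ basis  # (n_trains, t)
        drift = truth.train_drift_sd * u[:, :, None] * course[:, None, :]  # (n_trains, p, t)
        data += drift[train_idx]

    noise = rng.standard_normal((n, p, t))
    data += truth.noise_scale * np.einsum("pq,nqt->npt", chol, noise)

    return EpochsData(
        data=data,
        times=times.copy(),
        sfreq=1000.0 / (times[1] - times[0]),
        layout=layout,
        trials=rows.copy(),
        normalization_state="raw",
    )


@dataclass(frozen=True)
class ArtifactLog:
    corrupted: np.ndarray  # trial indices that received a spike
    below_threshold: bool  # True when the spike may survive rejection


def inject_artifacts(
    epochs: EpochsData,
    fraction: float,
    amplitude: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[EpochsData, ArtifactLog]:
    """Add high-amplitude spikes to a random subset of trials.

    Each corrupted trial receives a single-sample spike on one random sensor;
    the default amplitudes are twice the rejection thresholds, so the
    corrupted set is exactly the set a correct rejection pass removes.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    amplitude = dict(amplitude) if amplitude is not None else dict(DEFAULT_ARTIFACT_AMPLITUDE)
    rng = np.random.default_rng(seed)
    n = epochs.n_trials
    n_bad = int(round(fraction * n))
    out = epochs.copy()
    if n_bad == 0:
        return out, ArtifactLog(corrupted=np.array([], dtype=int), below_threshold=False)
    bad = np.sort(rng.choice(n, size=n_bad, replace=False))
    for idx in bad:
        sensor = int(rng.integers(epochs.layout.n_sensors))
        sample = int(rng.integers(epochs.n_times))
        kind = epochs.layout.sensor_type[sensor]
        out.data[idx, sensor, sample] += amplitude[kind]
    from .preprocess import RejectionCriteria  # local import to avoid a cycle

    thr = RejectionCriteria()
    below = amplitude[MAG] <= thr.mag_ptp_max or amplitude[GRAD] <= thr.grad_ptp_max
    return out, ArtifactLog(corrupted=bad, below_threshold=bool(below))
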