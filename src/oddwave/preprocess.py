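"""Trial rejection, low-pass filtering, and baseline z-normalization.

The pipeline order is reject -> filter -> normalize.  The container's
``normalization_state`` makes misordering detectable: rejection and filtering
demand raw epochs, and normalization flips the state so it cannot be applied
twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.filter import filter_data

from .containers import MAG, EpochsData

__all__ = [
    "RejectionCriteria",
    "PreprocConfig",
    "reject_artifacts",
    "lowpass_filter",
    "baseline_znormalize",
    "run_preprocessing",
]


@dataclass(frozen=True)
class RejectionCriteria:
    """Peak-to-peak amplitude limits per sensor type, plus the zero-signal rule.

    A trial is excluded when any magnetometer exceeds 10,000 fT peak-to-peak,
    any gradiometer exceeds 2,500 fT/cm, or (when ``reject_zero_signal``) all
    samples of all sensors are exactly zero.
    """

    mag_ptp_max: float = 10_000.0
    grad_ptp_max: float = 2_500.0
    reject_zero_signal: bool = True

    def __post_init__(self) -> None:
        if self.mag_ptp_max <= 0 or self.grad_ptp_max <= 0:
            raise ValueError("rejection thresholds must be positive")


@dataclass(frozen=True)
class PreprocConfig:
    lowpass_hz: float = 15.0
    transition_bandwidth_hz: float = 5.0
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    epoch_window: tuple[float, float] = (-200.0, 550.0)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        e0, e1 = self.epoch_window
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie inside the epoch window")


def reject_artifacts(
    epochs: EpochsData, criteria: RejectionCriteria | None = None
) -> tuple[EpochsData, pd.DataFrame]:
    """Drop trials violating the rejection criteria.

    Returns the surviving epochs (samples bitwise untouched, order preserved)
    and a log table with columns ``trial_index`` (positional index into the
    input) and ``reason``.
    """
    criteria = criteria if criteria is not None else RejectionCriteria()
    if epochs.normalization_state != "raw":
        raise ValueError("artifact rejection must run on raw (not normalized) epochs")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (n, p)
    thr = np.where(epochs.layout.type_mask(MAG), criteria.mag_ptp_max, criteria.grad_ptp_max)
    ptp_bad = (ptp > thr[None, :]).any(axis=1)
    zero_bad = np.zeros(epochs.n_trials, bool)
    if criteria.reject_zero_signal:
        zero_bad = (epochs.data == 0).all(axis=(1, 2))
    records = []
    for idx in np.flatnonzero(zero_bad | ptp_bad):
        reason = "zero_signal" if zero_bad[idx] else "ptp_exceeded"
        records.append((int(idx), reason))
    log = pd.DataFrame(records, columns=["trial_index", "reason"])
    keep = np.flatnonzero(~(zero_bad | ptp_bad))
    if keep.size == 0:
        raise ValueError("all trials rejected; downstream stages are undefined")
    return epochs.select_trials(keep), log


def lowpass_filter(epochs: EpochsData, config: PreprocConfig | None = None) -> EpochsData:
    """Zero-phase Hamming-window FIR low-pass (cutoff 15 Hz by default).

    DC gain is 1 and the filter is applied per sensor and per trial, so the
    latency structure of the evoked components is not biased.
    """
    config = config if config is not None else PreprocConfig()
    if config.lowpass_hz >= epochs.sfreq / 2:
        raise ValueError(
            f"cutoff {config.lowpass_hz} Hz must be below Nyquist ({epochs.sfreq / 2} Hz)"
        )
    filtered = filter_data(
        epochs.data,
        sfreq=epochs.sfreq,
        l_freq=None,
        h_freq=config.lowpass_hz,
        h_trans_bandwidth=config.transition_bandwidth_hz,
        fir_design="firwin",
        fir_window="hamming",
        phase="zero",
        verbose="error",
    )
    out = epochs.copy()
    out.data = filtered
    return out


def baseline_znormalize(epochs: EpochsData, config: PreprocConfig | None = None) -> EpochsData:
    """Per trial and per sensor, z-score by the prestimulus mean and SD."""
    config = config if config is not None else PreprocConfig()
    if epochs.normalization_state != "raw":
        raise ValueError("epochs are already z-normalized")
    b0, b1 = config.baseline_window
    mask = (epochs.times >= b0) & (epochs.times < b1)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    base = epochs.data[:, :, mask]
    mean = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=0, keepdims=True)
    zero = np.isclose(sd[:, :, 0], 0.0)
    if zero.any():
        trial, sensor = map(int, np.argwhere(zero)[0])
        raise ValueError(
            f"zero baseline SD at trial {trial}, sensor {sensor}; "
            "run artifact rejection before normalizing"
        )
    out = epochs.copy()
    out.data = (epochs.data - mean) / sd
    out.normalization_state = "z-normalized"
    return out


def run_preprocessing(
    epochs: EpochsData,
    criteria: RejectionCriteria | None = None,
    config: PreprocConfig | None = None,
) -> tuple[EpochsData, pd.DataFrame]:
    """Full pass in the canonical order: reject -> filter -> normalize."""
    kept, log = reject_artifacts(epochs, criteria)
    kept = lowpass_filter(kept, config)
    kept = baseline_znormalize(kept, config)
    return kept, log
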