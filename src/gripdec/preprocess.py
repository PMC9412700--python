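"""Preprocessing of raw glove angles into angular-velocity trials.

The glove's rotation sensors measure finger-joint angles only indirectly:
the mapping to anatomical joint angles depends on hand geometry and device
placement.  Two steps make the signal largely geometry-independent without
solving that mapping: (1) an affine normalization per channel against the
subject's calibration extrema, so a flat hand maps to 0 and full flexion to
1; and (2) taking the temporal derivative, i.e. angular velocity, which
removes posture offsets.  A 100 ms moving average suppresses sensor noise
before differencing, and the slow natural movements allow downsampling to
16 Hz to shrink the feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Calibration, Trial


@dataclass
class PreprocessParams:
    """Parameters of the raw-to-velocity pipeline.

    smoothing_window : moving-average width in seconds (default 0.1 s).
    target_rate      : output sample rate in Hz (default 16).
    """

    smoothing_window: float = 0.1
    target_rate: float = 16.0

    def __post_init__(self) -> None:
        if not self.smoothing_window > 0:
            raise ValueError("smoothing_window must be positive")
        if not self.target_rate > 0:
            raise ValueError("target_rate must be positive")


def normalize_calibration(trial: Trial, calib: Calibration) -> Trial:
    """Map raw sensor values through the per-channel calibration affine.

    y = (x - min) / (max - min), so the calibration minimum (flat hand)
    maps to 0 and the maximum (full flexion) to 1.  Values outside the
    calibrated range pass through the same affine map and may leave [0, 1].
    """
    if trial.stage != "raw":
        raise ValueError(f"expected a raw trial, got stage={trial.stage!r}")
    if trial.n_channels != calib.n_channels:
        raise ValueError("trial/calibration channel mismatch")
    span = calib.maximum - calib.minimum
    return trial.with_values((trial.values - calib.minimum) / span,
                             stage="normalized")


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    The window covers ``window_samples`` samples centered on the current
    index; for even widths the extra sample is taken from the past (the
    MATLAB ``movmean`` convention).  Edges average whatever samples fall
    inside the series, so output length equals input length.
    """
    w = int(window_samples)
    if w < 1:
        raise ValueError("window must cover at least one sample")
    t = values.shape[0]
    # window at index i covers [i - w//2, i + (w-1)//2], clamped
    lo = np.clip(np.arange(t) - w // 2, 0, t)
    hi = np.clip(np.arange(t) + (w - 1) // 2 + 1, 0, t)
    csum = np.concatenate([np.zeros((1,) + values.shape[1:]),
                           np.cumsum(values, axis=0)], axis=0)
    return (csum[hi] - csum[lo]) / (hi - lo).reshape(-1, *([1] * (values.ndim - 1)))


def smooth(trial: Trial, window: float = 0.1) -> Trial:
    """Apply the centered moving-average filter (``window`` in seconds)."""
    w = round(window * trial.sample_rate)
    if w < 1:
        raise ValueError("window shorter than one sample period")
    return trial.with_values(moving_average(trial.values, w))


def differentiate(trial: Trial) -> Trial:
    """Forward first difference scaled by the sample rate (units per second).

    Output has one sample fewer than the input.
    """
    if trial.n_samples < 2:
        raise ValueError("need at least 2 samples to differentiate")
    vel = np.diff(trial.values, axis=0) * trial.sample_rate
    return trial.with_values(vel, stage="velocity")


def downsample(trial: Trial, target_rate: float) -> Trial:
    """Linearly interpolate onto a uniform grid at ``target_rate``.

    The new grid spans the same time interval; the output length is
    floor((t - 1) * target / source) + 1.  Anti-alias filtering is assumed
    to have been applied by :func:`smooth`.
    """
    source = trial.sample_rate
    if target_rate > source:
        raise ValueError("target rate must not exceed the current rate")
    t = trial.n_samples
    n_out = int(np.floor((t - 1) * target_rate / source)) + 1
    t_old = np.arange(t) / source
    t_new = np.arange(n_out) / target_rate
    out = np.empty((n_out, trial.n_channels))
    for ch in range(trial.n_channels):
        out[:, ch] = np.interp(t_new, t_old, trial.values[:, ch])
    return trial.with_values(out, sample_rate=target_rate)


def preprocess_trial(trial: Trial, calib: Calibration,
                     params: PreprocessParams | None = None) -> Trial:
    """Full pipeline: normalize -> smooth -> differentiate -> downsample."""
    params = params or PreprocessParams()
    out = normalize_calibration(trial, calib)
    out = smooth(out, params.smoothing_window)
    out = differentiate(out)
    return downsample(out, params.target_rate)


def preprocess_dataset(dataset, params: PreprocessParams | None = None):
    """Preprocess every trial of a dataset against its subject calibration."""
    from .data import Dataset

    params = params or PreprocessParams()
    trials = [preprocess_trial(t, dataset.calibrations[t.subject_id], params)
              for t in dataset.trials]
    return Dataset(trials=trials, subjects=dict(dataset.subjects),
                   calibrations=dict(dataset.calibrations))
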