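"""Synthetic data-glove recordings with the study's experimental structure.

The simulator emulates sessions in which participants from a younger and an
older group perform six movement tasks — fingertip touching, clothes-peg
transfers, and clockwise/counter-clockwise turns of a large and a small
cube — each trial being a fixed D2->D5 sequence of four thumb-opposition
grips.  A session comprises ``runs`` runs of ``blocks_per_run`` blocks of
``trials_per_block`` repetitions, block k of every run carrying task k in
the standard block order, i.e. with the defaults 300 trials per subject.

Each grip is a raised-cosine flexion pulse (smooth and band-limited, like
natural hand movement) on a class-specific set of co-activating channels;
classes differ in which channels move, their amplitude ratios, pulse width
and plateau.  The two turning directions of the same cube differ only by
the sign of a small waveform-asymmetry parameter, deliberately making them
the hardest pair to separate.  Subjects differ in amplitude (proportional
to hand size), baseline sensor offsets, and tempo; older subjects are
slowed by a multiplicative factor and add extra per-grip amplitude jitter
(more rigid, more variable movement).  Additive Gaussian sensor noise
closes the model.

All randomness flows from one ``numpy.random.default_rng`` (PCG64) seeded
generator, so identical configs and seeds reproduce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CHANNEL_NAMES, N_CHANNELS, TASKS, Calibration, Dataset, \
    SubjectMeta, Trial

#: Hand length (cm) at which the amplitude scale factor is 1.
REFERENCE_HAND_SIZE = 18.5

#: Full-flexion sensor span in device units for the reference hand.
DEVICE_GAIN = 30.0


@dataclass
class SyntheticConfig:
    """Knobs of the simulator; defaults reproduce the study's session shape."""

    n_subjects_per_group: int = 17
    runs: int = 5
    blocks_per_run: int = 6
    trials_per_block: int = 10
    sample_rate: float = 100.0
    base_duration: float = 8.0       # seconds per 4-grip sequence (2 s/grip)
    duration_jitter: float = 0.1     # CV of per-trial duration
    noise_sd: float = 0.02           # sensor noise, fraction of amplitude
    hand_size_young: tuple[float, float] = (16.5, 21.0)   # cm
    hand_size_old: tuple[float, float] = (16.0, 20.5)
    tempo_slowdown_old: float = 1.2
    waveform_jitter: float = 0.03    # per-grip amplitude CV, young
    waveform_jitter_old_extra: float = 0.03
    equalize_classes: bool = False   # null model: identical kinematics per class
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "runs", "blocks_per_run",
                     "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.base_duration <= 0:
            raise ValueError("noise_sd must be >= 0 and base_duration > 0")


@dataclass
class ClassKinematicModel:
    """Waveform recipe of one task: per-grip channel weights and pulse shape."""

    activation: np.ndarray          # (4 grips, 15 channels), weights in [0, 1]
    pulse_width: float = 0.5        # fraction of the grip slot under the pulse
    plateau: float = 0.0            # fraction of the pulse held at peak
    asymmetry: float = 0.0          # >0 skews the pulse late, <0 early

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape != (4, N_CHANNELS):
            raise ValueError("activation must be (4, 15)")


def _ch(digit: int, joint: int) -> int:
    return CHANNEL_NAMES.index(f"D{digit}J{joint}")


def _weights(finger: tuple[float, float, float],
             thumb: tuple[float, float, float],
             coact: float, grip_scales: tuple[float, ...]) -> np.ndarray:
    """Per-grip channel weights: grip g opposes the thumb with digit g+2."""
    w = np.full((4, N_CHANNELS), coact)
    for g in range(4):
        digit = g + 2
        for j in range(3):
            w[g, _ch(1, j + 1)] = thumb[j]
            w[g, _ch(digit, j + 1)] = finger[j]
        w[g] *= grip_scales[g]
    return w


def default_class_models() -> dict[str, ClassKinematicModel]:
    """Distinct kinematic recipes per task; cw/ccw pairs differ only by the
    sign of the waveform asymmetry."""
    models = {
        "fingertip_touching": ClassKinematicModel(
            _weights((1.0, 0.9, 0.8), (0.5, 0.4, 0.3), 0.05, (1, 1, 1, 1)),
            pulse_width=0.45),
        "clothes_peg": ClassKinematicModel(
            _weights((0.95, 0.45, 0.25), (0.6, 0.5, 0.4), 0.1, (1, 0.95, 0.9, 0.95)),
            pulse_width=0.75, plateau=0.5),
        "rubiks_cw": ClassKinematicModel(
            _weights((0.8, 0.6, 0.5), (0.7, 0.5, 0.3), 0.3, (0.9, 1, 1, 0.9)),
            pulse_width=0.6, plateau=0.2, asymmetry=0.22),
        "small_rubiks_cw": ClassKinematicModel(
            _weights((0.9, 0.85, 0.7), (0.8, 0.6, 0.5), 0.2, (1, 0.9, 1, 0.9)),
            pulse_width=0.5, plateau=0.1, asymmetry=0.22),
    }
    for cw in ("rubiks_cw", "small_rubiks_cw"):
        m = models[cw]
        models[cw.replace("_cw", "_ccw")] = ClassKinematicModel(
            m.activation.copy(), m.pulse_width, m.plateau, -m.asymmetry)
    return {task: models[task] for task in TASKS}


def _pulse(u: np.ndarray, width: float, plateau: float,
           asym: float) -> np.ndarray:
    """Raised-cosine flexion pulse on the unit grip slot.

    ``u`` is slot-relative time in [0, 1]; the pulse occupies the central
    ``width`` fraction, optionally holding its peak for a ``plateau``
    fraction of the pulse; ``asym`` skews rise vs fall by warping pulse
    time with an exponential-of-asym power law.
    """
    start = (1.0 - width) / 2.0
    v = (u - start) / width
    out = np.zeros_like(u)
    inside = (v >= 0) & (v <= 1)
    vv = v[inside] ** np.exp(asym)
    r = (1.0 - plateau) / 2.0
    y = np.empty_like(vv)
    rise = vv < r
    hold = (vv >= r) & (vv <= r + plateau)
    fall = vv > r + plateau
    y[rise] = 0.5 * (1 - np.cos(np.pi * vv[rise] / r))
    y[hold] = 1.0
    y[fall] = 0.5 * (1 + np.cos(np.pi * (vv[fall] - r - plateau) / r))
    out[inside] = y
    return out


def _trial_activation(model: ClassKinematicModel, n_samples: int,
                      grip_jitter: np.ndarray) -> np.ndarray:
    """Noise-free normalized activation (n_samples x 15) in [0, 1]."""
    u = np.linspace(0.0, 4.0, n_samples, endpoint=False)
    act = np.zeros((n_samples, N_CHANNELS))
    for g in range(4):
        slot = (u >= g) & (u < g + 1)
        pulse = _pulse(u[slot] - g, model.pulse_width, model.plateau,
                       model.asymmetry)
        act[slot] += np.outer(pulse, model.activation[g] * grip_jitter[g])
    return np.clip(act, 0.0, 1.0)


def generate_calibration(amplitude: float,
                         offsets: np.ndarray | float = 0.0) -> Calibration:
    """Calibration extrema implied by a subject's amplitude and offsets:
    per channel, min = resting offset and max = min + full-flexion span."""
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float),
                              (N_CHANNELS,)).copy()
    return Calibration(minimum=offsets, maximum=offsets + amplitude)


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Simulate a full multi-subject session; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    models = default_class_models()
    if config.equalize_classes:
        common = models["fingertip_touching"]
        models = {task: common for task in TASKS}

    dataset = Dataset()
    n_young = config.n_subjects_per_group
    n_total = 2 * n_young
    for si in range(n_total):
        sid = f"S{si + 1:02d}"
        group = "young" if si < n_young else "old"
        lo, hi = (config.hand_size_young if group == "young"
                  else config.hand_size_old)
        hand_size = float(rng.uniform(lo, hi))
        age = float(rng.uniform(22, 37) if group == "young"
                    else rng.uniform(62, 80))
        dataset.subjects[sid] = SubjectMeta(sid, age, group, hand_size)

        amp = DEVICE_GAIN * hand_size / REFERENCE_HAND_SIZE
        offsets = rng.uniform(5.0, 15.0, size=N_CHANNELS)
        dataset.calibrations[sid] = generate_calibration(amp, offsets)

        tempo = float(np.exp(rng.normal(0.0, 0.08)))
        if group == "old":
            tempo *= config.tempo_slowdown_old
        wf_jitter = config.waveform_jitter
        if group == "old":
            wf_jitter += config.waveform_jitter_old_extra

        for run in range(1, config.runs + 1):
            for block in range(1, config.blocks_per_run + 1):
                task = TASKS[(block - 1) % len(TASKS)]
                model = models[task]
                for _ in range(config.trials_per_block):
                    dur = config.base_duration * tempo * (
                        1.0 + config.duration_jitter * rng.standard_normal())
                    dur = max(dur, 0.3 * config.base_duration)
                    n = max(int(round(dur * config.sample_rate)), 8)
                    grip_jitter = 1.0 + wf_jitter * rng.standard_normal(4)
                    act = _trial_activation(model, n,
                                            np.clip(grip_jitter, 0.2, 1.0))
                    raw = offsets + amp * act
                    if config.noise_sd > 0:
                        raw = raw + rng.normal(
                            0.0, config.noise_sd * amp, size=raw.shape)
                    dataset.trials.append(Trial(
                        values=raw, sample_rate=config.sample_rate,
                        subject_id=sid, run=run, block=block, task=task,
                        stage="raw"))
    dataset.validate()
    return dataset
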