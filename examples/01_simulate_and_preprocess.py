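"""Simulate a small glove session and preprocess it to angular velocity.

Generates two subjects (one young, one old) performing one run of the six
movement tasks, then runs the raw-to-velocity chain: calibration
normalization, 100 ms moving average, temporal derivative, downsampling to
16 Hz.
"""

import gripdec as gd

cfg = gd.SyntheticConfig(n_subjects_per_group=1, runs=1, noise_sd=0.02, seed=42)
raw = gd.generate_dataset(cfg)
print(f"simulated {raw.n_trials} trials from {len(raw.subjects)} subjects")
for sid in raw.subject_ids:
    m = raw.subjects[sid]
    print(f"  {sid}: {m.age_group:5s} age {m.age:.0f}, hand {m.hand_size:.1f} cm")

t = raw.trials[0]
print(f"first trial: task={t.task}, {t.n_samples} samples x {t.n_channels} "
      f"channels at {t.sample_rate:.0f} Hz ({t.duration:.2f} s)")

vel = gd.preprocess_dataset(raw)
v = vel.trials[0]
print(f"after preprocessing: {v.n_samples} samples at {v.sample_rate:.0f} Hz, "
      f"stage={v.stage}")
print(f"velocity range: [{v.values.min():.3f}, {v.values.max():.3f}] 1/s")
# Trial lengths vary because subjects move at their own tempo; the velocity
# signal is what the decoders consume.
lengths = sorted({tr.n_samples for tr in vel.trials})
print(f"velocity trial lengths range {lengths[0]}..{lengths[-1]} samples")
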