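"""Featurize raw band-limited signals into DE tensors.

Builds a small synthetic raw dataset whose gamma-band amplitude doubles on
class-specific channels, extracts differential-entropy features with 1-s
Hamming windows, and shows that the active (band, channel) pairs sit about
ln 2 ~ 0.693 nats above the rest — the expected elevation for a 2x amplitude
(4x variance) change.
"""

import numpy as np

from sgcsrm.features import DEFAULT_BANDS, extract_feature_tensor, normalize_subject
from sgcsrm.synthetic import SyntheticSpec, generate_raw_dataset

spec = SyntheticSpec(
    n_subjects=2, trials_per_class_per_subject=4, bands=("alpha", "gamma"), seed=0
)
recordings, truth = generate_raw_dataset(spec, fs=200.0, trial_s=20.0)
bands = tuple(b for b in DEFAULT_BANDS if b.name in spec.bands)
tensor = extract_feature_tensor(recordings, bands, kind="DE", window_s=1.0)
print(f"feature tensor (trials, channels, bands, windows): {tensor.values.shape}")

band_idx, ch = truth.active_pairs[0][0]
rows = tensor.labels == 0
elevation = (
    tensor.values[rows, ch, band_idx].mean() - tensor.values[~rows, ch, band_idx].mean()
)
print(
    f"DE elevation on an active (band, channel) pair: {elevation:.3f} nats "
    f"(theory: ln 2 = {np.log(2):.3f})"
)

normalized = normalize_subject(tensor)
print(
    "after per-subject standardization, per-feature mean ~ "
    f"{np.abs(normalized.values.mean(axis=0)).max():.2e} and std ~ 1"
)
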