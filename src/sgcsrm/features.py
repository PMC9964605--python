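"""Band-power featurization of multichannel EEG trials.

Raw trials are cut into non-overlapping 1-s segments; each segment is
Hamming-windowed, Fourier-transformed, and the power spectral density is
integrated over each canonical frequency band to give a per-window band
variance (the PSD feature).  The differential-entropy (DE) feature is the
Gaussian differential entropy of that variance, 0.5*ln(2*pi*e*sigma^2), in
nats.  Trials are zero-padded (or truncated) to a common window count and
standardized per subject before any cross-validation split, so each subject
is normalized against itself only and no information crosses the
train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_BANDS",
    "BAND_PRESETS",
    "SEED12_CHANNELS",
    "CHANNEL_PRESETS",
    "RawRecording",
    "BandDefinition",
    "BandFeatureTensor",
    "window_band_variance",
    "differential_entropy",
    "extract_feature_tensor",
    "pad_or_truncate",
    "normalize_subject",
    "select_channels",
    "select_bands",
]

#: Class order used everywhere: index 0/1/2 = negative/neutral/positive.
CLASS_NAMES: tuple[str, str, str] = ("negative", "neutral", "positive")

_VAR_EPS = 1e-8  # clamp for variances entering the DE log
_STD_EPS = 1e-8  # guard for zero-variance features in normalization


@dataclass(frozen=True)
class BandDefinition:
    """One canonical EEG frequency band."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)

#: Band-subset presets: the four emotion-salient bands, and all five.
BAND_PRESETS: dict[str, tuple[str, ...]] = {
    "four": ("theta", "alpha", "beta", "gamma"),
    "all": ("delta", "theta", "alpha", "beta", "gamma"),
}

#: The 12 temporal-area channels suited to emotion classification.
SEED12_CHANNELS: tuple[str, ...] = (
    "FT7", "T7", "TP7", "P7", "C5", "CP5",
    "FT8", "T8", "TP8", "P8", "C6", "CP6",
)

CHANNEL_PRESETS: dict[str, tuple[str, ...]] = {"seed12": SEED12_CHANNELS}


@dataclass(frozen=True)
class RawRecording:
    """One EEG trial: channels x time samples, in microvolts."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str
    trial_id: str
    label: str  # one of CLASS_NAMES

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 2 or samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"samples shape {samples.shape} does not match "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.label not in CLASS_NAMES:
            raise ValueError(f"label must be one of {CLASS_NAMES}, got {self.label!r}")


@dataclass
class BandFeatureTensor:
    """Trial x channel x band x window feature array with axis labels."""

    values: np.ndarray  # (N, C, B, D)
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]
    subject_ids: np.ndarray  # (N,) str
    labels: np.ndarray  # (N,) int in {0, 1, 2}
    feature_kind: str = "DE"  # "DE" | "PSD"
    trial_ids: np.ndarray | None = None
    n_windows: np.ndarray | None = None  # pre-padding window counts

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels)
        n, c, b, _ = self.values.shape
        if c != len(self.channel_names) or b != len(self.band_names):
            raise ValueError("axis lengths do not match name lists")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("per-trial metadata length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.feature_kind not in ("DE", "PSD"):
            raise ValueError("feature_kind must be 'DE' or 'PSD'")

    @property
    def window_count(self) -> int:
        return self.values.shape[3]

    def copy_with(self, **kwargs) -> "BandFeatureTensor":
        base = dict(
            values=self.values,
            channel_names=self.channel_names,
            band_names=self.band_names,
            subject_ids=self.subject_ids,
            labels=self.labels,
            feature_kind=self.feature_kind,
            trial_ids=self.trial_ids,
            n_windows=self.n_windows,
        )
        base.update(kwargs)
        return BandFeatureTensor(**base)


def window_band_variance(
    recording: RawRecording, band: BandDefinition, window_s: float = 1.0
) -> np.ndarray:
    """Per-channel, per-window band variance of a trial.

    Each non-overlapping window of ``window_s`` seconds is Hamming-windowed;
    the band variance is the periodogram PSD integrated over the band, so a
    white signal of total variance v yields roughly v * bandwidth / Nyquist.
    A partial trailing window is discarded.

    Returns an array of shape (channels, windows).
    """
    nper = int(round(window_s * recording.fs))
    n_samples = recording.samples.shape[1]
    if n_samples < nper:
        raise ValueError(
            f"trial too short: {n_samples} samples < one window of {nper}"
        )
    if band.hi >= recording.fs / 2:
        raise ValueError(
            f"band exceeds Nyquist: {band.name} hi={band.hi} >= fs/2={recording.fs / 2}"
        )
    n_windows = n_samples // nper
    segs = recording.samples[:, : n_windows * nper].reshape(
        recording.samples.shape[0], n_windows, nper
    )
    freqs, psd = periodogram(segs, fs=recording.fs, window="hamming", axis=-1)
    # half-open bins so the integrated width equals hi - lo at 1-Hz resolution
    in_band = (freqs >= band.lo) & (freqs < band.hi)
    if not np.any(in_band):
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] contains no frequency bin")
    df = freqs[1] - freqs[0]
    return psd[:, :, in_band].sum(axis=-1) * df


def differential_entropy(variance) -> np.ndarray:
    """Gaussian differential entropy 0.5*ln(2*pi*e*sigma^2), in nats."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("nonpositive variance")
    return 0.5 * np.log(2.0 * np.pi * np.e * variance)


def extract_feature_tensor(
    recordings: list[RawRecording],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    kind: str = "DE",
    window_s: float = 1.0,
) -> BandFeatureTensor:
    """Featurize a set of trials into a (trial, channel, band, window) tensor.

    All recordings must share a sampling rate and channel set.  Trials with
    fewer windows than the longest are zero-padded on the right; the
    pre-padding window count of each trial is kept in ``n_windows``.
    """
    if kind not in ("DE", "PSD"):
        raise ValueError("kind must be 'DE' or 'PSD'")
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].fs
    channels = recordings[0].channel_names
    for rec in recordings[1:]:
        if rec.fs != fs:
            raise ValueError(f"mixed sampling rates: {rec.fs} != {fs}")
        if rec.channel_names != channels:
            raise ValueError("mixed channel sets across recordings")
    per_trial: list[np.ndarray] = []
    for rec in recordings:
        bands_v = np.stack(
            [window_band_variance(rec, band, window_s) for band in bands], axis=1
        )  # (C, B, D_trial)
        if kind == "DE":
            bands_v = differential_entropy(np.maximum(bands_v, _VAR_EPS))
        per_trial.append(bands_v)
    d_max = max(v.shape[2] for v in per_trial)
    n_windows = np.array([v.shape[2] for v in per_trial])
    values = np.zeros((len(per_trial), len(channels), len(bands), d_max))
    for i, v in enumerate(per_trial):
        values[i, :, :, : v.shape[2]] = v
    return BandFeatureTensor(
        values=values,
        channel_names=channels,
        band_names=tuple(b.name for b in bands),
        subject_ids=np.array([r.subject_id for r in recordings]),
        labels=np.array([CLASS_NAMES.index(r.label) for r in recordings]),
        feature_kind=kind,
        trial_ids=np.array([r.trial_id for r in recordings]),
        n_windows=n_windows,
    )


def pad_or_truncate(tensor: BandFeatureTensor, target_windows: int = 265) -> BandFeatureTensor:
    """Zero-pad (right) or truncate (from the end) to a fixed window count."""
    if target_windows < 1:
        raise ValueError("target_windows must be >= 1")
    n, c, b, d = tensor.values.shape
    if d == target_windows:
        return tensor
    if d < target_windows:
        values = np.zeros((n, c, b, target_windows))
        values[..., :d] = tensor.values
    else:
        values = tensor.values[..., :target_windows].copy()
    return tensor.copy_with(values=values)


def normalize_subject(tensor: BandFeatureTensor) -> BandFeatureTensor:
    """Standardize each (channel, band, window) feature within each subject.

    Uses the population standard deviation over the subject's trials;
    features with (near) zero variance map to 0.
    """
    values = tensor.values.copy()
    for subject in np.unique(tensor.subject_ids):
        rows = tensor.subject_ids == subject
        block = values[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        safe = np.where(sd > _STD_EPS, sd, 1.0)
        normed = (block - mu) / safe
        normed[:, sd <= _STD_EPS] = 0.0
        values[rows] = normed
    return tensor.copy_with(values=values)


def select_channels(tensor: BandFeatureTensor, wanted) -> BandFeatureTensor:
    """Reduce/reorder the channel axis; ``wanted`` may be a preset name."""
    if isinstance(wanted, str):
        if wanted not in CHANNEL_PRESETS:
            raise KeyError(f"unknown channel preset {wanted!r}; presets: {list(CHANNEL_PRESETS)}")
        wanted = CHANNEL_PRESETS[wanted]
    index = {name: i for i, name in enumerate(tensor.channel_names)}
    missing = [name for name in wanted if name not in index]
    if missing:
        raise KeyError(f"channels not in tensor: {missing}")
    rows = [index[name] for name in wanted]
    return tensor.copy_with(values=tensor.values[:, rows], channel_names=tuple(wanted))


def select_bands(tensor: BandFeatureTensor, wanted) -> BandFeatureTensor:
    """Reduce/reorder the band axis; ``wanted`` may be a preset ('four'/'all')."""
    if isinstance(wanted, str):
        if wanted not in BAND_PRESETS:
            raise KeyError(f"unknown band preset {wanted!r}; presets: {list(BAND_PRESETS)}")
        wanted = BAND_PRESETS[wanted]
    index = {name: i for i, name in enumerate(tensor.band_names)}
    missing = [name for name in wanted if name not in index]
    if missing:
        raise KeyError(f"bands not in tensor: {missing}")
    cols = [index[name] for name in wanted]
    return tensor.copy_with(values=tensor.values[:, :, cols], band_names=tuple(wanted))
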