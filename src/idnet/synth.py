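"""Synthetic multichannel EEG with planted pairwise coupling.

The generative model mirrors the assumption the identifiability method rests
on: each channel has unique private dynamics (a resonant AR(2) process with a
channel-specific spectral peak), and functional coupling between two channels
is modelled as a latent *shared* AR(2) source mixed into both, eroding their
uniqueness.  Sensor crosstalk adds a small linear leak between channels and
white noise degrades everything.  Planted couplings are returned as ground
truth so network-recovery can be validated.

Channel i's pre-mixing signal is::

    x_i = (1 - min(1, sum_j c_ij)) * private_i + sum_j c_ij * shared_ij + noise

with each component normalised to unit variance, so ``c_ij`` is the variance
share the pair (i, j) draws from its common source.  At ``c_ij = 1`` (and no
other couplings) the two channels are exchangeable up to noise; at
``c_ij = 0`` they are fully private.

All randomness is keyed hierarchically on (seed, group, subject, condition,
stream), so regenerating a subject is independent of how many other subjects
exist, and a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError
from .preprocess import CONDITIONS, Recording

#: warm-up samples discarded from every AR(2) realisation
_BURN_IN = 500

# stream tags for hierarchical RNG keying
_STREAM_PRIVATE = 0
_STREAM_SHARED = 1
_STREAM_NOISE = 2
_STREAM_JITTER = 3
_STREAM_PAIRFREQ = 4


@dataclass(frozen=True)
class ChannelDynamics:
    """Private AR(2) fingerprint of one channel.

    ``frequency`` (Hz) sets the spectral peak, ``damping`` in (0, 1) its
    sharpness (poles at radius ``damping``).
    """

    frequency: float
    damping: float = 0.98


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort.

    Defaults describe a desk-scale resting-state-like cohort: 10 channels at
    250 Hz for 60 s, 5 subjects per group, 2 groups, two conditions, channel
    fingerprints spread over 5-40 Hz, weak uniform crosstalk and moderate
    sensor noise.
    """

    n_channels: int = 10
    n_subjects: int = 5
    n_groups: int = 2
    sampling_rate: float = 250.0
    duration: float = 60.0
    coupling: np.ndarray | None = None  # (C, C) symmetric in [0, 1], zero diag
    channel_dynamics: list[ChannelDynamics] | None = None
    crosstalk: float | np.ndarray = 0.05  # scalar -> uniform off-diagonal mixing
    noise_sd: float = 0.5
    subject_jitter: float = 0.05  # +-5% resonance-frequency jitter per subject
    seed: int = 0
    conditions: tuple[str, str] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels: need at least 2 channels")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects: need at least 1 subject")
        if self.n_groups < 1:
            raise ConfigurationError("n_groups: need at least 1 group")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate: must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration: must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be non-negative")
        if self.coupling is None:
            self.coupling = np.zeros((self.n_channels, self.n_channels))
        self.coupling = np.asarray(self.coupling, dtype=float)
        c = self.coupling
        if c.shape != (self.n_channels, self.n_channels):
            raise ConfigurationError(
                f"coupling: shape {c.shape} != ({self.n_channels}, {self.n_channels})"
            )
        if not np.allclose(c, c.T):
            raise ConfigurationError("coupling: matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ConfigurationError("coupling: diagonal must be zero")
        if np.any((c < 0) | (c > 1)):
            raise ConfigurationError("coupling: entries must lie in [0, 1]")
        if self.channel_dynamics is None:
            freqs = np.linspace(5.0, 40.0, self.n_channels)
            self.channel_dynamics = [ChannelDynamics(float(f)) for f in freqs]
        if len(self.channel_dynamics) != self.n_channels:
            raise ConfigurationError(
                "channel_dynamics: one (frequency, damping) entry per channel required"
            )
        for d in self.channel_dynamics:
            if not 0 < d.damping < 1:
                raise ConfigurationError("channel_dynamics: damping must be in (0, 1)")
            if not 0 < d.frequency < self.sampling_rate / 2:
                raise ConfigurationError(
                    "channel_dynamics: frequency must be below Nyquist"
                )
        if np.isscalar(self.crosstalk):
            x = float(self.crosstalk)
            if not 0 <= x < 1:
                raise ConfigurationError("crosstalk: must be in [0, 1)")
            m = np.full((self.n_channels, self.n_channels), x)
            np.fill_diagonal(m, 0.0)
            self.crosstalk = m
        else:
            self.crosstalk = np.asarray(self.crosstalk, dtype=float)
            if self.crosstalk.shape != (self.n_channels, self.n_channels):
                raise ConfigurationError("crosstalk: wrong shape")
            if np.any((self.crosstalk < 0) | (self.crosstalk >= 1)):
                raise ConfigurationError("crosstalk: entries must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def channel_labels(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]


@dataclass
class GroundTruthCoupling:
    """Planted coupling strength per unordered channel pair (validation only)."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: SynthConfig) -> "GroundTruthCoupling":
        labels = config.channel_labels
        pairs = {
            (labels[i], labels[j]): float(config.coupling[i, j])
            for i in range(config.n_channels)
            for j in range(i + 1, config.n_channels)
        }
        return cls(pairs)

    def to_edge_list(self, path: str | Path) -> Path:
        """Write the ground truth as a tab-separated edge list."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = ["channel_a\tchannel_b\tcoupling"]
        lines += [f"{a}\t{b}\t{c:.6g}" for (a, b), c in sorted(self.pairs.items())]
        path.write_text("\n".join(lines) + "\n")
        return path


def _rng(config: SynthConfig, *key: int) -> np.random.Generator:
    """Hierarchically keyed RNG stream; independent of sibling streams."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *map(int, key)]))


def _ar2(rng: np.random.Generator, n: int, frequency: float, damping: float,
         sampling_rate: float) -> np.ndarray:
    """Unit-variance resonant AR(2) realisation (poles damping*e^{+-i*2*pi*f/fs})."""
    a1 = 2.0 * damping * np.cos(2.0 * np.pi * frequency / sampling_rate)
    a2 = -damping * damping
    x = lfilter([1.0], [1.0, -a1, -a2], rng.standard_normal(n + _BURN_IN))[_BURN_IN:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _condition_index(config: SynthConfig, condition: str) -> int:
    try:
        return config.conditions.index(condition)
    except ValueError:
        raise ConfigurationError(
            f"condition: {condition!r} not in {config.conditions}"
        ) from None


def _subject_frequencies(config: SynthConfig, group_index: int,
                         subject_index: int) -> np.ndarray:
    """Per-subject jittered resonance frequencies (same for both conditions)."""
    base = np.array([d.frequency for d in config.channel_dynamics])
    rng = _rng(config, group_index, subject_index, _STREAM_JITTER)
    jitter = rng.uniform(-config.subject_jitter, config.subject_jitter, size=base.shape)
    return base * (1.0 + jitter)


def _pair_frequency(config: SynthConfig, group_index: int, i: int, j: int) -> float:
    """Shared-source frequency for pair (i, j): drawn between the two private peaks."""
    fi = config.channel_dynamics[i].frequency
    fj = config.channel_dynamics[j].frequency
    rng = _rng(config, group_index, _STREAM_PAIRFREQ, i, j)
    lo, hi = sorted((fi, fj))
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def generate_recording(
    config: SynthConfig,
    subject_index: int,
    group_index: int,
    condition: str,
) -> Recording:
    """Generate one subject/condition recording.

    Deterministic given ``(config.seed, subject_index, group_index,
    condition)``.  See the module docstring for the mixing model.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError("subject_index: out of range")
    if not 0 <= group_index < config.n_groups:
        raise ConfigurationError("group_index: out of range")
    cond_idx = _condition_index(config, condition)
    n = config.n_samples
    freqs = _subject_frequencies(config, group_index, subject_index)
    damps = np.array([d.damping for d in config.channel_dynamics])

    private = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        rng = _rng(config, group_index, subject_index, cond_idx, _STREAM_PRIVATE, ch)
        private[ch] = _ar2(rng, n, freqs[ch], damps[ch], config.sampling_rate)

    signals = np.zeros((config.n_channels, n))
    total_coupling = np.minimum(config.coupling.sum(axis=1), 1.0)
    for ch in range(config.n_channels):
        signals[ch] = (1.0 - total_coupling[ch]) * private[ch]

    for i in range(config.n_channels):
        for j in range(i + 1, config.n_channels):
            c = config.coupling[i, j]
            if c == 0:
                continue
            f_shared = _pair_frequency(config, group_index, i, j)
            damp = 0.5 * (damps[i] + damps[j])
            rng = _rng(config, group_index, subject_index, cond_idx, _STREAM_SHARED, i, j)
            shared = _ar2(rng, n, f_shared, damp, config.sampling_rate)
            signals[i] += c * shared
            signals[j] += c * shared

    if config.noise_sd > 0:
        for ch in range(config.n_channels):
            rng = _rng(config, group_index, subject_index, cond_idx, _STREAM_NOISE, ch)
            signals[ch] = signals[ch] + config.noise_sd * rng.standard_normal(n)

    # sensor crosstalk: linear leak of every other channel into each sensor
    mixed = signals + config.crosstalk @ signals

    return Recording(
        data=mixed,
        sampling_rate=config.sampling_rate,
        channel_labels=config.channel_labels,
        subject_id=f"g{group_index}s{subject_index}",
        group=f"group{group_index}",
        condition=condition,
    )


def generate_group(
    config: SynthConfig, group_index: int
) -> tuple[list[Recording], GroundTruthCoupling]:
    """All recordings of one group: n_subjects x two conditions."""
    recordings = [
        generate_recording(config, s, group_index, cond)
        for s in range(config.n_subjects)
        for cond in config.conditions
    ]
    return recordings, GroundTruthCoupling.from_config(config)


def coupling_matrix_from_pairs(
    n_channels: int, pairs: dict[tuple[int, int], float]
) -> np.ndarray:
    """Build a symmetric coupling matrix from {(i, j): strength} entries."""
    m = np.zeros((n_channels, n_channels))
    for (i, j), c in pairs.items():
        m[i, j] = m[j, i] = c
    return m


def write_group(
    config: SynthConfig,
    group_index: int,
    out_dir: str | Path,
    format: str = "delimited",
) -> list[Path]:
    """Generate one group and write recordings plus the ground-truth edge list."""
    from .preprocess import save_recording

    out_dir = Path(out_dir)
    recordings, truth = generate_group(config, group_index)
    ext = ".npy" if format == "binary-array" else ".tsv"
    paths = [
        save_recording(
            rec, out_dir / f"{rec.subject_id}_{rec.condition}{ext}", format=format
        )
        for rec in recordings
    ]
    paths.append(truth.to_edge_list(out_dir / f"group{group_index}_ground_truth.tsv"))
    return paths
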