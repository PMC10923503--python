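"""Recording I/O, band-pass filtering and segmentation.

A :class:`Recording` is one subject/condition multichannel time series
(channels x samples).  Channels are cut into nonoverlapping fixed-length
segments; the segments of every channel of a subject/condition are kept
aligned in *slots* (slot k = samples ``[k*L, (k+1)*L)``), which downstream
code relies on both for the paired train/test split and for the per-segment
correlation baseline.

File format: a delimited text matrix (rows = channels) or a ``.npy`` binary
array, plus a JSON sidecar ``<stem>.meta.json`` carrying sampling rate,
channel labels, subject, group and condition.  EDF import is available when
``mne`` is installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import DataError, FormatError, LabelError, ParameterError

logger = logging.getLogger(__name__)

CONDITIONS = ("eyes_open", "eyes_closed")

#: default segment length in samples; 1,000 points is the field's common
#: compromise between segment informativeness and segment count.
DEFAULT_SEGMENT_LENGTH = 1000


@dataclass
class Recording:
    """One subject/condition multichannel recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes, one row per channel.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : list of str
        Unique, ordered channel names (row order of ``data``).
    subject_id : str
    group : str
        Cohort label (e.g. ``control``/``patient``).
    condition : str
        ``eyes_open``, ``eyes_closed`` or ``all``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str = "s0"
    group: str = "g0"
    condition: str = "all"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("recording data must be a 2-D channels x samples array")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise LabelError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise LabelError("duplicate channel labels")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise LabelError(f"unknown channel {label!r}") from None
        return self.data[idx]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band; ``low``/``high`` of ``None`` means broadband (no filtering)."""

    name: str
    low: float | None = None
    high: float | None = None

    @property
    def is_broadband(self) -> bool:
        return self.low is None and self.high is None

    def validate(self, sampling_rate: float) -> None:
        if self.is_broadband:
            return
        if self.low is None or self.high is None:
            raise ParameterError(f"band {self.name!r}: both edges required")
        if not 0 < self.low < self.high:
            raise ParameterError(f"band {self.name!r}: need 0 < low < high")
        if self.high >= sampling_rate / 2:
            raise ParameterError(
                f"band {self.name!r}: high edge {self.high} Hz >= Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


#: The classical EEG analysis bands used throughout, plus broadband.
STANDARD_BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband"),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta1": BandSpec("beta1", 13.0, 20.0),
    "beta2": BandSpec("beta2", 20.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 50.0),
}


def get_band(band: str | BandSpec) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return STANDARD_BANDS[band]
    except KeyError:
        raise ParameterError(
            f"unknown band {band!r}; known: {sorted(STANDARD_BANDS)}"
        ) from None


def bandpass(rec: Recording, band: str | BandSpec) -> Recording:
    """Zero-phase band-pass filter a recording.

    A 4th-order Butterworth filter applied forward and backward
    (``sosfiltfilt``), so the pass band is attenuated twice and no phase
    distortion is introduced.  Broadband returns the input unchanged.
    """
    band = get_band(band)
    if band.is_broadband:
        return rec
    band.validate(rec.sampling_rate)
    sos = butter(
        4, [band.low, band.high], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def segment_channel(series: np.ndarray, length: int) -> np.ndarray:
    """Cut a 1-D series into nonoverlapping consecutive segments.

    Returns an array of shape ``(floor(len/length), length)``; the trailing
    remainder is discarded.  Segment k covers samples ``[k*length, (k+1)*length)``.
    """
    series = np.asarray(series, dtype=float)
    if length < 2:
        raise ParameterError("segment length must be >= 2")
    n = series.shape[0] // length
    if n == 0:
        raise DataError(
            f"series of {series.shape[0]} samples shorter than one segment ({length})"
        )
    return series[: n * length].reshape(n, length)


@dataclass
class SegmentBank:
    """Aligned segments for a set of channels pooled over recordings.

    ``segments[c, k]`` is channel c's segment in slot k; all channels of one
    slot come from the same time window of the same recording, so slots are
    the exchangeable unit for train/test splitting and surrogate resampling.
    """

    segments: np.ndarray  # (n_channels, n_slots, L)
    channels: list[str]
    provenance: list[tuple[str, str]]  # (subject_id, condition) per slot
    sampling_rate: float

    @property
    def n_slots(self) -> int:
        return self.segments.shape[1]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise LabelError(f"unknown channel {label!r}") from None

    def subset_slots(self, slot_indices: np.ndarray) -> "SegmentBank":
        return SegmentBank(
            segments=self.segments[:, slot_indices],
            channels=list(self.channels),
            provenance=[self.provenance[i] for i in slot_indices],
            sampling_rate=self.sampling_rate,
        )


@dataclass
class PairDataset:
    """Balanced two-class dataset for one channel pair.

    ``a_segments[k]`` and ``b_segments[k]`` come from the same slot, so the
    dataset is balanced by construction and slot-level splits keep
    time-aligned segments in the same half.
    """

    a_segments: np.ndarray  # (n_slots, L)
    b_segments: np.ndarray
    channel_a: str
    channel_b: str
    provenance: list[tuple[str, str]]
    segment_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.a_segments.shape != self.b_segments.shape:
            raise DataError("pair dataset halves have different shapes")
        if self.a_segments.shape[0] == 0:
            raise DataError(
                f"no segments for pair ({self.channel_a}, {self.channel_b})"
            )
        self.segment_length = int(self.a_segments.shape[1])

    @property
    def n_slots(self) -> int:
        return self.a_segments.shape[0]

    @property
    def labels(self) -> tuple[str, str]:
        return (self.channel_a, self.channel_b)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All segments stacked with 0/1 class indices (0 = channel_a)."""
        x = np.vstack([self.a_segments, self.b_segments])
        y = np.concatenate(
            [np.zeros(self.n_slots, dtype=int), np.ones(self.n_slots, dtype=int)]
        )
        return x, y


def build_segment_bank(
    recordings: Sequence[Recording],
    channels: Sequence[str] | None = None,
    length: int = DEFAULT_SEGMENT_LENGTH,
    condition_filter: str = "all",
    band: str | BandSpec = "broadband",
    zscore: bool = False,
) -> SegmentBank:
    """Filter, segment and pool recordings into an aligned segment bank.

    Filtering is applied to the continuous signal before segmentation to
    avoid per-segment edge effects.  ``condition_filter='all'`` pools both
    conditions; otherwise only matching recordings are kept.  ``zscore``
    standardises each segment (mean 0, sd 1) — off by default.
    """
    recs = [
        r
        for r in recordings
        if condition_filter == "all" or r.condition == condition_filter
    ]
    if not recs:
        raise DataError(f"no recordings match condition {condition_filter!r}")
    if channels is None:
        channels = list(recs[0].channel_labels)
    channels = list(channels)
    groups = {r.group for r in recs}
    if len(groups) > 1:
        raise DataError(f"recordings span multiple groups: {sorted(groups)}")
    rate = recs[0].sampling_rate
    blocks: list[np.ndarray] = []
    provenance: list[tuple[str, str]] = []
    for rec in recs:
        if rec.sampling_rate != rate:
            raise DataError("recordings have inconsistent sampling rates")
        filtered = bandpass(rec, band)
        per_channel = [segment_channel(filtered.channel(ch), length) for ch in channels]
        block = np.stack(per_channel, axis=0)  # (C, n_slots, L)
        blocks.append(block)
        provenance.extend([(rec.subject_id, rec.condition)] * block.shape[1])
    segments = np.concatenate(blocks, axis=1)
    if zscore:
        mu = segments.mean(axis=2, keepdims=True)
        sd = segments.std(axis=2, keepdims=True)
        sd[sd == 0] = 1.0
        segments = (segments - mu) / sd
    return SegmentBank(segments, channels, provenance, rate)


def pair_dataset(bank: SegmentBank, channel_a: str, channel_b: str) -> PairDataset:
    """Extract one channel pair's balanced dataset from a segment bank."""
    ia, ib = bank.channel_index(channel_a), bank.channel_index(channel_b)
    return PairDataset(
        a_segments=bank.segments[ia],
        b_segments=bank.segments[ib],
        channel_a=channel_a,
        channel_b=channel_b,
        provenance=list(bank.provenance),
    )


def assemble_pair_dataset(
    recordings: Sequence[Recording],
    channel_a: str,
    channel_b: str,
    length: int = DEFAULT_SEGMENT_LENGTH,
    condition_filter: str = "all",
    band: str | BandSpec = "broadband",
) -> PairDataset:
    """Pool one channel pair's segments across subjects of a group."""
    bank = build_segment_bank(
        recordings, [channel_a, channel_b], length, condition_filter, band
    )
    return pair_dataset(bank, channel_a, channel_b)


# ---------------------------------------------------------------------------
# file I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_recording(rec: Recording, path: str | Path, format: str = "delimited") -> Path:
    """Write a recording plus its JSON metadata sidecar.

    ``delimited`` writes a tab-separated channels x samples matrix;
    ``binary-array`` writes a ``.npy`` file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        np.savetxt(path, rec.data, delimiter="\t")
    elif format == "binary-array":
        np.save(path, rec.data)
        if path.suffix != ".npy":
            path = path.with_suffix(path.suffix + ".npy")
    else:
        raise FormatError(f"unknown format {format!r}")
    meta = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "condition": rec.condition,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a recording written by :func:`save_recording`, or an EDF file.

    ``format`` is inferred from the suffix when not given (``.npy`` ->
    binary, ``.edf`` -> EDF, otherwise delimited).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = {
            ".npy": "binary-array",
            ".edf": "edf",
        }.get(path.suffix.lower(), "delimited")
    if format == "edf":
        return _load_edf(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if format == "binary-array":
        data = np.load(path)
    elif format == "delimited":
        try:
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-rectangular or non-numeric data in {path}: {exc}")
    else:
        raise FormatError(f"unknown format {format!r}")
    return Recording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta["channel_labels"]),
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "g0")),
        condition=str(meta.get("condition", "all")),
    )


def _load_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError:  # pragma: no cover - optional dependency
        raise FormatError("EDF import requires the optional 'mne' dependency")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )
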