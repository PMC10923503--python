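"""Pooled-group null ensembles, percentile bands and Z-score curves.

The significance reference for group-level metric curves: surrogate
networks are rebuilt from scratch on segment banks that mix all groups
together, so any group-specific structure is destroyed while the marginal
properties of the data (channel count, segment count, spectral content of
the pool) are preserved.  Observed curves are compared against the
ensemble's 10-90 percentile band and expressed as Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, ParameterError
from .identifiability import identifiability_from_bank
from .models import ModelSpec
from .netbuild import DEFAULT_DENSITIES, density_sweep, weights_from_scores
from .preprocess import BandSpec, Recording, SegmentBank, build_segment_bank
from .topology import ALL_METRICS, MetricCurve, metric_curves


@dataclass
class NullEnsemble:
    """Surrogate metric values per (metric, density) cell."""

    metrics: list[str]
    densities: list[float]
    values: dict[tuple[str, float], np.ndarray]
    n_surrogates: int
    pooling: str = ""

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if len(v) != self.n_surrogates:
                raise DataError(f"cell {key}: {len(v)} values != {self.n_surrogates}")

    def cell(self, metric: str, density: float) -> np.ndarray:
        key = (metric, round(float(density), 6))
        if key not in self.values:
            raise AlignmentError(f"no null cell for metric={metric} density={density}")
        return self.values[key]


@dataclass
class ZScoreCurve:
    """(observed - null mean) / null sd per density; nan where sd = 0."""

    metric_name: str
    densities: list[float]
    z_values: list[float]
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "metric": self.metric_name,
                "density": self.densities,
                "z": self.z_values,
            }
        )


def _pooled_bank(
    group_banks: Sequence[SegmentBank],
) -> tuple[SegmentBank, int]:
    """Concatenate group banks slot-wise; target count = smallest group's."""
    first = group_banks[0]
    for b in group_banks[1:]:
        if b.channels != first.channels:
            raise DataError("groups disagree on channels")
        if b.segment_length != first.segment_length:
            raise DataError("groups disagree on segment length")
    pooled = SegmentBank(
        segments=np.concatenate([b.segments for b in group_banks], axis=1),
        channels=list(first.channels),
        provenance=[p for b in group_banks for p in b.provenance],
        sampling_rate=first.sampling_rate,
    )
    n_target = min(b.n_slots for b in group_banks)
    return pooled, n_target


def _surrogate_bank(
    pooled: SegmentBank,
    n_target: int,
    rng: np.random.Generator,
    granularity: str,
) -> SegmentBank:
    if granularity == "segment":
        idx = rng.choice(pooled.n_slots, size=n_target, replace=False)
        return pooled.subset_slots(np.sort(idx))
    if granularity == "subject":
        subjects = sorted({p[0] for p in pooled.provenance})
        order = rng.permutation(len(subjects))
        chosen: list[int] = []
        for si in order:
            subj = subjects[si]
            slots = [i for i, p in enumerate(pooled.provenance) if p[0] == subj]
            chosen.extend(slots)
            if len(chosen) >= n_target:
                break
        if len(chosen) < n_target:
            raise DataError("insufficient pooled segments for subject-level surrogate")
        return pooled.subset_slots(np.array(sorted(chosen[:n_target])))
    raise ParameterError(f"granularity {granularity!r} (use 'segment' or 'subject')")


def build_null_ensemble(
    group_recordings: Mapping[str, Sequence[Recording]],
    channels: Sequence[str] | None = None,
    specs: Sequence[ModelSpec] | None = None,
    length: int = 1000,
    band: str | BandSpec = "broadband",
    condition_filter: str = "all",
    densities: Sequence[float] = DEFAULT_DENSITIES,
    metrics: Sequence[str] | None = None,
    n_iterations: int = 10,
    n_surrogates: int = 100,
    seed: int = 0,
    granularity: str = "segment",
) -> NullEnsemble:
    """Build the pooled-group null ensemble.

    Each surrogate draws a group-sized set of segment slots uniformly from
    the pooled groups (slot alignment across channels preserved), runs the
    full identifiability -> thresholding -> metrics pipeline on it, and
    records every (metric, density) value.  ``granularity='subject'`` draws
    whole subjects instead of individual slots.
    """
    if len(group_recordings) < 2:
        raise DataError("null ensemble requires at least 2 groups")
    if n_surrogates < 10:
        raise ParameterError("n_surrogates must be >= 10")
    if metrics is None:
        metrics = list(ALL_METRICS)
    if specs is None:
        from .models import default_specs

        specs = default_specs(length, models=("knn_fallback",))
    banks = [
        build_segment_bank(recs, channels, length, condition_filter, band)
        for recs in group_recordings.values()
    ]
    pooled, n_target = _pooled_bank(banks)
    densities = [round(float(d), 6) for d in densities]
    cells: dict[tuple[str, float], list[float]] = {
        (m, d): [] for m in metrics for d in densities
    }
    for s in range(n_surrogates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), s]))
        bank = _surrogate_bank(pooled, n_target, rng, granularity)
        mat = identifiability_from_bank(
            bank, specs, n_iterations, seed=[int(seed), s, 1], keep_table=False
        )
        nets = density_sweep(weights_from_scores(mat), densities)
        curves = metric_curves(nets, metrics, seed=seed)
        for curve in curves:
            for d, v in zip(densities, curve.values):
                cells[(curve.metric_name, d)].append(v)
    return NullEnsemble(
        metrics=list(metrics),
        densities=densities,
        values={k: np.asarray(v) for k, v in cells.items()},
        n_surrogates=n_surrogates,
        pooling=f"{granularity}-level uniform draw from "
        f"{len(group_recordings)} pooled groups, {n_target} slots each",
    )


def percentile_band(
    ens: NullEnsemble, lo: float = 10.0, hi: float = 90.0
) -> dict[tuple[str, float], tuple[float, float]]:
    """Empirical (lo, hi) percentiles per cell, linear interpolation between
    order statistics; undefined surrogate values are ignored."""
    out = {}
    for key, vals in ens.values.items():
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            out[key] = (UNDEFINED_BAND, UNDEFINED_BAND)
            continue
        p = np.percentile(finite, [lo, hi], method="linear")
        out[key] = (float(p[0]), float(p[1]))
    return out


UNDEFINED_BAND = float("nan")


def zscore(observed: MetricCurve, ens: NullEnsemble) -> ZScoreCurve:
    """Z-score curve of an observed metric against the null ensemble.

    Requires the observed curve's density grid to match the ensemble's;
    cells with zero null variance give nan, never +-inf.
    """
    obs_d = [round(float(d), 6) for d in observed.densities]
    if obs_d != ens.densities:
        raise AlignmentError(
            f"density grids differ: observed {obs_d} vs null {ens.densities}"
        )
    zs = []
    for d, x in zip(obs_d, observed.values):
        vals = ens.cell(observed.metric_name, d)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0 or not np.isfinite(x):
            zs.append(float("nan"))
            continue
        mu, sd = float(np.mean(finite)), float(np.std(finite))
        zs.append((x - mu) / sd if sd > 0 else float("nan"))
    return ZScoreCurve(observed.metric_name, obs_d, zs, group=observed.group)


def band_coverage(
    curves: Sequence[MetricCurve],
    ens: NullEnsemble,
    lo: float = 10.0,
    hi: float = 90.0,
) -> float:
    """Fraction of defined (metric, density) cells whose observed value lies
    inside the [lo, hi] null percentile band (a calibration diagnostic)."""
    band = percentile_band(ens, lo, hi)
    inside = total = 0
    for curve in curves:
        for d, x in zip(curve.densities, curve.values):
            key = (curve.metric_name, round(float(d), 6))
            b = band.get(key)
            if b is None or not np.isfinite(x) or not np.isfinite(b[0]):
                continue
            total += 1
            inside += int(b[0] <= x <= b[1])
    if total == 0:
        raise DataError("no defined cells to assess coverage on")
    return inside / total
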