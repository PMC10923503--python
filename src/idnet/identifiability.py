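"""Pairwise channel identifiability.

The core statistic: for every unordered pair of channels, a supervised
classifier is repeatedly trained to tell the two channels' segments apart on
a random half of the segment slots and scored on the other half; the mean
accuracy per model over iterations is taken, and the best model's mean is
the pair's *identifiability*.  High scores mean unique, easily recognised
dynamics; low scores mean the channels share dynamics — which is exactly
what is interpreted as functional connectivity downstream.

The random half-split operates on aligned segment *slots*: both channels'
segments from the same time window always land in the same half.  Because
strongly coupled channels yield time-aligned near-duplicate segments,
splitting each channel independently would leak near-copies of test segments
into the training set under the wrong label and push instance-based
classifiers systematically below chance; the slot-level split preserves the
chance-level limit for exchangeable pairs and keeps both halves exactly
balanced.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .models import REGISTRY_ORDER, ModelSpec, fit_and_score
from .preprocess import (
    BandSpec,
    PairDataset,
    Recording,
    SegmentBank,
    build_segment_bank,
    get_band,
    pair_dataset,
)

logger = logging.getLogger(__name__)

#: iterations of the train/evaluate cycle per pair and model; one hundred
#: gives very stable means, small test profiles use ten.
DEFAULT_N_ITERATIONS = 100


def _as_seed_key(seed: int | Sequence[int]) -> list[int]:
    return [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]


def _derived_int_seed(*key: int) -> int:
    # keep derived seeds below 2**31 for downstream consumers
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


@dataclass
class ScoreTable:
    """Long-format record of every (pair, model, iteration) score."""

    table: pd.DataFrame  # columns: channel_a, channel_b, model, iteration, score
    n_iterations: int

    def __post_init__(self) -> None:
        counts = self.table.groupby(["channel_a", "channel_b", "model"]).size()
        if len(counts) and not (counts == self.n_iterations).all():
            raise DataError("score table must hold n_iterations entries per (pair, model)")

    def mean_scores(self) -> pd.DataFrame:
        return (
            self.table.groupby(["channel_a", "channel_b", "model"], as_index=False)[
                "score"
            ].mean()
        )


def half_split(
    n_slots: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half partition of slot indices (train, test)."""
    if n_slots < 2:
        raise DataError("need at least 2 segment slots for a half-split")
    order = rng.permutation(n_slots)
    half = n_slots // 2
    return order[:half], order[half:]


def score_pair(
    ds: PairDataset,
    specs: Sequence[ModelSpec],
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int | Sequence[int] = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Iterated half-split scores for one channel pair.

    Every iteration draws a fresh random half/half split of the slots (shared
    by all models, so models are compared on identical splits) and trains and
    evaluates each model once.  Returns per-model mean scores over iterations
    and the long-format score rows.
    """
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    if ds.n_slots < 4:
        raise DataError(
            f"pair ({ds.channel_a}, {ds.channel_b}): {ds.n_slots} segment slots "
            "is too few for a half-split with both classes on each side"
        )
    key = _as_seed_key(seed)
    rows: list[dict] = []
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([*key, it]))
        tr, te = half_split(ds.n_slots, rng)
        x_train = np.vstack([ds.a_segments[tr], ds.b_segments[tr]])
        y_train = np.r_[np.zeros(len(tr), dtype=int), np.ones(len(tr), dtype=int)]
        x_test = np.vstack([ds.a_segments[te], ds.b_segments[te]])
        y_test = np.r_[np.zeros(len(te), dtype=int), np.ones(len(te), dtype=int)]
        for mi, spec in enumerate(specs):
            seeded = spec.with_seed(_derived_int_seed(*key, it, mi))
            score = fit_and_score(
                seeded, x_train, y_train, x_test, y_test, classes=ds.labels
            )
            rows.append(
                {
                    "channel_a": ds.channel_a,
                    "channel_b": ds.channel_b,
                    "model": spec.architecture,
                    "iteration": it,
                    "score": score,
                }
            )
    table = pd.DataFrame(rows)
    means = table.groupby("model")["score"].mean().to_dict()
    return means, table


def best_score(per_model_means: dict[str, float]) -> tuple[float, str]:
    """Maximum mean score and its model; ties broken by registry order."""
    if not per_model_means:
        raise ParameterError("best_score requires at least one model mean")
    order = {name: i for i, name in enumerate(REGISTRY_ORDER)}
    best = max(
        per_model_means.items(),
        key=lambda kv: (kv[1], -order.get(kv[0], len(order))),
    )
    return float(best[1]), best[0]


@dataclass
class IdentifiabilityMatrix:
    """Symmetric matrix of best per-pair classification scores.

    ``scores[i, j]`` is the best model's mean accuracy for channels i and j
    (diagonal is NaN: self-pairs are not computed); ``best_model[i, j]``
    names that model.
    """

    channels: list[str]
    scores: np.ndarray
    best_model: np.ndarray  # dtype object, None on the diagonal
    group: str = ""
    condition: str = "all"
    band: str = "broadband"
    score_table: ScoreTable | None = None

    def __post_init__(self) -> None:
        n = len(self.channels)
        if self.scores.shape != (n, n):
            raise DataError("score matrix shape does not match channel count")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.scores[off], self.scores.T[off], equal_nan=True):
            raise DataError("score matrix must be symmetric")

    def pair_score(self, a: str, b: str) -> float:
        i, j = self.channels.index(a), self.channels.index(b)
        return float(self.scores[i, j])

    def pair_frame(self) -> pd.DataFrame:
        """One row per unordered pair: channel_a, channel_b, score, best model."""
        rows = [
            {
                "channel_a": self.channels[i],
                "channel_b": self.channels[j],
                "score": float(self.scores[i, j]),
                "best_model": self.best_model[i, j],
            }
            for i, j in itertools.combinations(range(len(self.channels)), 2)
        ]
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.channels, columns=self.channels)

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="nan")


def identifiability_from_bank(
    bank: SegmentBank,
    specs: Sequence[ModelSpec],
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int | Sequence[int] = 0,
    group: str = "",
    condition: str = "all",
    band: str = "broadband",
    keep_table: bool = True,
) -> IdentifiabilityMatrix:
    """Identifiability matrix from an already-built segment bank."""
    channels = bank.channels
    n = len(channels)
    if n < 2:
        raise DataError("need at least 2 channels")
    key = _as_seed_key(seed)
    scores = np.full((n, n), np.nan)
    best = np.full((n, n), None, dtype=object)
    tables: list[pd.DataFrame] = []
    for p, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        ds = pair_dataset(bank, channels[i], channels[j])
        try:
            means, table = score_pair(ds, specs, n_iterations, seed=[*key, p])
        except DataError as exc:
            raise DataError(f"pair ({channels[i]}, {channels[j]}): {exc}") from exc
        s, m = best_score(means)
        scores[i, j] = scores[j, i] = s
        best[i, j] = best[j, i] = m
        if keep_table:
            tables.append(table)
    score_table = (
        ScoreTable(pd.concat(tables, ignore_index=True), n_iterations)
        if keep_table
        else None
    )
    return IdentifiabilityMatrix(
        channels=list(channels),
        scores=scores,
        best_model=best,
        group=group,
        condition=condition,
        band=band,
        score_table=score_table,
    )


def identifiability_matrix(
    recordings: Sequence[Recording],
    channels: Sequence[str] | None = None,
    specs: Sequence[ModelSpec] | None = None,
    length: int = 1000,
    band: str | BandSpec = "broadband",
    condition_filter: str = "all",
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    keep_table: bool = True,
) -> IdentifiabilityMatrix:
    """Identifiability matrix for one group of recordings.

    Segments are pooled across all subjects of the group (and across both
    conditions when ``condition_filter='all'``), so the result is a single
    matrix per group/condition, not per subject.
    """
    if specs is None:
        from .models import default_specs

        specs = default_specs(length)
    band = get_band(band)
    bank = build_segment_bank(recordings, channels, length, condition_filter, band)
    group = recordings[0].group if recordings else ""
    return identifiability_from_bank(
        bank,
        specs,
        n_iterations,
        seed,
        group=group,
        condition=condition_filter,
        band=band.name,
        keep_table=keep_table,
    )


def correlation_from_bank(bank: SegmentBank) -> np.ndarray:
    """Mean absolute Pearson correlation per channel pair over aligned slots.

    Slots where either channel's segment has zero variance are excluded from
    that pair's average (with a logged warning).  Diagonal is 1.
    """
    n = len(bank.channels)
    out = np.eye(n)
    segs = bank.segments
    sd = segs.std(axis=2)
    centred = segs - segs.mean(axis=2, keepdims=True)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (sd[i] > 0) & (sd[j] > 0)
            n_bad = int((~valid).sum())
            if n_bad:
                logger.warning(
                    "pair (%s, %s): excluding %d zero-variance segment slots",
                    bank.channels[i],
                    bank.channels[j],
                    n_bad,
                )
            if not valid.any():
                out[i, j] = out[j, i] = np.nan
                continue
            L = bank.segment_length
            r = (centred[i, valid] * centred[j, valid]).sum(axis=1) / (
                L * sd[i, valid] * sd[j, valid]
            )
            out[i, j] = out[j, i] = float(np.abs(r).mean())
    return out


def correlation_baseline(
    recordings: Sequence[Recording],
    channels: Sequence[str] | None = None,
    length: int = 1000,
    condition_filter: str = "all",
    band: str | BandSpec = "broadband",
) -> pd.DataFrame:
    """Per-pair mean |Pearson r| over aligned segments, as a labelled matrix.

    The classical linear-correlation counterpart of the identifiability
    matrix: across pairs the two are expected to associate negatively.
    """
    bank = build_segment_bank(recordings, channels, length, condition_filter, band)
    m = correlation_from_bank(bank)
    return pd.DataFrame(m, index=bank.channels, columns=bank.channels)


def band_profile(
    recordings: Sequence[Recording],
    channels: Sequence[str] | None = None,
    bands: Sequence[str | BandSpec] = ("broadband", "alpha", "beta1", "beta2", "gamma"),
    specs: Sequence[ModelSpec] | None = None,
    length: int = 1000,
    condition_filter: str = "all",
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Identifiability score distribution per frequency band.

    Reruns the full pairwise analysis on band-filtered signals; returns the
    long-format per-pair scores and the per-band median score.
    """
    frames = []
    medians: dict[str, float] = {}
    for b in bands:
        band = get_band(b)
        mat = identifiability_matrix(
            recordings,
            channels,
            specs,
            length,
            band,
            condition_filter,
            n_iterations,
            seed,
            keep_table=False,
        )
        pf = mat.pair_frame()
        pf.insert(0, "band", band.name)
        frames.append(pf)
        medians[band.name] = float(pf["score"].median())
    return pd.concat(frames, ignore_index=True), medians
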