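"""End-to-end pipeline: generate/ingest -> score -> networks -> metrics -> nulls.

A single :class:`RunConfig` drives every stage; each stage writes its
artifacts under the output directory and the run finishes with a manifest
(JSON) listing every artifact with a SHA-256 hash plus the config snapshot,
so a run is reproducible and individually re-runnable per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .identifiability import band_profile, correlation_from_bank, identifiability_from_bank
from .models import DEFAULT_MODELS, default_specs
from .netbuild import DEFAULT_DENSITIES, density_sweep, weights_from_scores
from .nullmodels import build_null_ensemble, percentile_band, zscore
from .preprocess import build_segment_bank, load_recording
from .synth import SynthConfig, generate_group
from .topology import ALL_METRICS, curves_to_frame, metric_curves

logger = logging.getLogger(__name__)

STAGES = ("generate", "score", "network", "metrics", "null")


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``synthetic`` (a :class:`SynthConfig` or its field dict) or
    ``data_dirs`` (group label -> directory of recording files) must be
    given.  ``seed`` is mandatory and feeds every random stage.
    """

    seed: int
    out_dir: str = "idnet_run"
    synthetic: SynthConfig | dict | None = None
    data_dirs: dict[str, str] = field(default_factory=dict)
    channels: list[str] | None = None
    conditions: list[str] = field(default_factory=lambda: ["all"])
    bands: list[str] = field(default_factory=lambda: ["broadband"])
    segment_length: int = 1000
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    hyperparams: dict[str, dict] = field(default_factory=dict)
    n_iterations: int = 100
    densities: list[float] = field(default_factory=lambda: list(DEFAULT_DENSITIES))
    metrics: list[str] = field(default_factory=lambda: list(ALL_METRICS))
    n_surrogates: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed: mandatory")
        if isinstance(self.synthetic, dict):
            self.synthetic = SynthConfig(**self.synthetic)
        if self.synthetic is None and not self.data_dirs:
            raise ConfigurationError("synthetic or data_dirs: one input source required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.synthetic, SynthConfig):
            syn = dataclasses.asdict(self.synthetic)
            for k, v in syn.items():
                if isinstance(v, np.ndarray):
                    syn[k] = v.tolist()
            syn["channel_dynamics"] = [
                {"frequency": c.frequency, "damping": c.damping}
                for c in self.synthetic.channel_dynamics
            ]
            d["synthetic"] = syn
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful executor for one configured run."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, str] = {}
        self.groups: dict[str, list] = {}
        self.matrices: dict[tuple[str, str, str], Any] = {}
        self.sweeps: dict[tuple[str, str, str], list] = {}
        self.curves: dict[tuple[str, str, str], list] = {}

    # -- stages ------------------------------------------------------------

    def generate(self) -> None:
        cfg = self.config
        if cfg.synthetic is not None:
            syn = cfg.synthetic
            for g in range(syn.n_groups):
                recs, truth = generate_group(syn, g)
                name = f"group{g}"
                self.groups[name] = recs
                path = truth.to_edge_list(self.out / f"{name}_ground_truth.tsv")
                self._register(path)
        else:
            for name, directory in cfg.data_dirs.items():
                directory = Path(directory)
                if not directory.is_dir():
                    raise DataError(f"missing group directory for {name!r}: {directory}")
                files = sorted(
                    p
                    for p in directory.iterdir()
                    if p.suffix.lower() in (".tsv", ".txt", ".csv", ".npy", ".edf")
                    and (
                        p.suffix.lower() == ".edf"
                        or p.with_suffix(p.suffix + ".meta.json").exists()
                    )
                )
                if not files:
                    raise DataError(f"group {name!r}: no recording files in {directory}")
                self.groups[name] = [load_recording(p) for p in files]
        logger.info("stage generate: %d groups", len(self.groups))

    def score(self) -> None:
        cfg = self.config
        specs = default_specs(
            cfg.segment_length, tuple(cfg.models), seed=cfg.seed,
            hyperparams=cfg.hyperparams,
        )
        for gi, (gname, recs) in enumerate(sorted(self.groups.items())):
            for ci, cond in enumerate(cfg.conditions):
                for bi, band in enumerate(cfg.bands):
                    bank = build_segment_bank(
                        recs, cfg.channels, cfg.segment_length, cond, band
                    )
                    mat = identifiability_from_bank(
                        bank,
                        specs,
                        cfg.n_iterations,
                        seed=[cfg.seed, gi, ci, bi],
                        group=gname,
                        condition=cond,
                        band=band,
                    )
                    self.matrices[(gname, cond, band)] = mat
                    stem = f"{gname}_{cond}_{band}"
                    p = self.out / f"{stem}_scores.tsv"
                    mat.save(p)
                    self._register(p)
                    p = self.out / f"{stem}_best_model.tsv"
                    pd.DataFrame(
                        mat.best_model, index=mat.channels, columns=mat.channels
                    ).to_csv(p, sep="\t")
                    self._register(p)
                    if mat.score_table is not None:
                        p = self.out / f"{stem}_score_table.tsv"
                        mat.score_table.table.to_csv(p, sep="\t", index=False)
                        self._register(p)
                    corr = pd.DataFrame(
                        correlation_from_bank(bank),
                        index=bank.channels,
                        columns=bank.channels,
                    )
                    p = self.out / f"{stem}_correlation.tsv"
                    corr.to_csv(p, sep="\t")
                    self._register(p)
        logger.info("stage score: %d matrices", len(self.matrices))

    def network(self) -> None:
        for key, mat in self.matrices.items():
            w = weights_from_scores(mat)
            stem = "_".join(key)
            p = self.out / f"{stem}_weights.tsv"
            pd.DataFrame(w.weights, index=w.nodes, columns=w.nodes).to_csv(p, sep="\t")
            self._register(p)
            nets = density_sweep(w, self.config.densities)
            self.sweeps[key] = nets
            for net in nets:
                d = net.target_density if net.target_density is not None else net.density
                p = net.save_edge_list(self.out / "networks" / f"{stem}_d{d:.2f}.tsv")
                self._register(p)
                p = net.save_graphml(self.out / "networks" / f"{stem}_d{d:.2f}.graphml")
                self._register(p)
        logger.info("stage network: %d sweeps", len(self.sweeps))

    def metrics(self) -> None:
        frames = []
        for (gname, cond, band), nets in self.sweeps.items():
            curves = metric_curves(
                nets,
                self.config.metrics,
                seed=self.config.seed,
                group=gname,
                condition=cond,
                band=band,
            )
            self.curves[(gname, cond, band)] = curves
            frames.append(curves_to_frame(curves))
        p = self.out / "metric_curves.tsv"
        pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False)
        self._register(p)

    def null(self) -> None:
        cfg = self.config
        if len(self.groups) < 2:
            logger.info("stage null: skipped (single group)")
            return
        specs = default_specs(
            cfg.segment_length, tuple(cfg.models), seed=cfg.seed,
            hyperparams=cfg.hyperparams,
        )
        rows, zrows = [], []
        for ci, cond in enumerate(cfg.conditions):
            for bi, band in enumerate(cfg.bands):
                ens = build_null_ensemble(
                    self.groups,
                    cfg.channels,
                    specs,
                    cfg.segment_length,
                    band,
                    cond,
                    cfg.densities,
                    cfg.metrics,
                    cfg.n_iterations,
                    cfg.n_surrogates,
                    seed=int(
                        np.random.SeedSequence([cfg.seed, 7, ci, bi]).generate_state(1)[0]
                        >> 1
                    ),
                )
                bandp = percentile_band(ens)
                for (metric, d), (lo, hi) in sorted(bandp.items()):
                    rows.append(
                        {
                            "condition": cond,
                            "band": band,
                            "metric": metric,
                            "density": d,
                            "p10": lo,
                            "p90": hi,
                        }
                    )
                for gname in self.groups:
                    for curve in self.curves.get((gname, cond, band), []):
                        zc = zscore(curve, ens)
                        zf = zc.to_frame()
                        zf.insert(1, "condition", cond)
                        zf.insert(2, "band", band)
                        zrows.append(zf)
        p = self.out / "null_bands.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        self._register(p)
        if zrows:
            p = self.out / "zscores.tsv"
            pd.concat(zrows, ignore_index=True).to_csv(p, sep="\t", index=False)
            self._register(p)

    # -- driver ------------------------------------------------------------

    def _register(self, path: Path) -> None:
        self.artifacts[str(path.relative_to(self.out))] = _sha256(path)

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        order = [s for s in STAGES if s in stages]
        for stage in order:
            try:
                getattr(self, stage)()
            except Exception as exc:
                raise type(exc)(f"stage {stage!r}: {exc}") from exc
        manifest = {
            "config": self.config.snapshot(),
            "artifacts": dict(sorted(self.artifacts.items())),
        }
        mpath = self.out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the configured stages and return the run manifest."""
    return PipelineRun(config).run(stages)


def render_report(manifest_path: str | Path) -> list[Path]:
    """Render figure-style summaries from a completed run's tables.

    Produces identifiability heatmaps and group-difference heatmaps,
    best-model maps, score-vs-correlation scatters, per-band score medians
    and metric/Z curves with null bands.  All numbers are read back from the
    manifest's tables; nothing is recomputed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest_path = Path(manifest_path)
    out = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    artifacts = manifest["artifacts"]
    missing = [a for a in artifacts if not (out / a).exists()]
    if missing:
        raise DataError(f"incomplete manifest; missing artifacts: {missing}")
    figures: list[Path] = []
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    score_mats = {
        a: pd.read_csv(out / a, sep="\t", index_col=0)
        for a in artifacts
        if a.endswith("_scores.tsv")
    }
    for name, df in score_mats.items():
        stem = name[: -len("_scores.tsv")]
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(df.values, vmin=0.5, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(df)), df.index, fontsize=6)
        ax.set_title(f"identifiability: {stem}")
        fig.colorbar(im, ax=ax, label="classification score")
        p = fig_dir / f"{stem}_identifiability.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        figures.append(p)

    names = sorted(score_mats)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if score_mats[a].shape != score_mats[b].shape:
                continue
            diff = score_mats[a].values - score_mats[b].values
            fig, ax = plt.subplots(figsize=(5, 4))
            lim = np.nanmax(np.abs(diff)) or 1.0
            im = ax.imshow(diff, vmin=-lim, vmax=lim, cmap="coolwarm")
            ax.set_title(f"{a[:-11]} - {b[:-11]}", fontsize=8)
            fig.colorbar(im, ax=ax, label="score difference")
            p = fig_dir / f"diff_{i}_{names.index(b)}.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            figures.append(p)

    for a in artifacts:
        if not a.endswith("_correlation.tsv"):
            continue
        stem = a[: -len("_correlation.tsv")]
        score_name = f"{stem}_scores.tsv"
        if score_name not in artifacts:
            continue
        corr = pd.read_csv(out / a, sep="\t", index_col=0).values
        scores = score_mats[score_name].values
        iu = np.triu_indices_from(corr, 1)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(scores[iu], corr[iu], s=12, alpha=0.7)
        ax.set_xlabel("classification score")
        ax.set_ylabel("mean |Pearson r|")
        ax.set_title(stem, fontsize=8)
        p = fig_dir / f"{stem}_score_vs_correlation.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        figures.append(p)

    curves_file = out / "metric_curves.tsv"
    if curves_file.exists():
        curves = pd.read_csv(curves_file, sep="\t")
        bands_file = out / "null_bands.tsv"
        nulls = pd.read_csv(bands_file, sep="\t") if bands_file.exists() else None
        for (cond, band), sub in curves.groupby(["condition", "band"]):
            metrics = sorted(sub["metric"].unique())
            ncol = min(4, len(metrics))
            nrow = int(np.ceil(len(metrics) / ncol))
            fig, axes = plt.subplots(
                nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False
            )
            for k, metric in enumerate(metrics):
                ax = axes[k // ncol][k % ncol]
                if nulls is not None:
                    nb = nulls[
                        (nulls["condition"] == cond)
                        & (nulls["band"] == band)
                        & (nulls["metric"] == metric)
                    ].sort_values("density")
                    if len(nb):
                        ax.fill_between(
                            nb["density"], nb["p10"], nb["p90"], color="0.85",
                            label="null 10-90",
                        )
                for g, gs in sub[sub["metric"] == metric].groupby("group"):
                    gs = gs.sort_values("density")
                    ax.plot(gs["density"], gs["value"], marker="o", ms=3, label=g)
                ax.set_title(metric, fontsize=8)
                ax.set_xlabel("link density", fontsize=7)
            axes[0][0].legend(fontsize=6)
            fig.suptitle(f"{cond} / {band}", fontsize=9)
            fig.tight_layout()
            p = fig_dir / f"curves_{cond}_{band}.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            figures.append(p)
    return figures
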