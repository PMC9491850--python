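"""End-to-end experiments: simulate -> window -> reduce -> train -> assess.

An :class:`ExperimentConfig` fully determines every artifact (the global seed
is propagated to the generator, the network and noise injection); runs are
reproducible byte-for-byte.  The train/validation/test split is
chronological with a one-window guard gap so overlapping windows never leak
across splits.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .drsn import DrsnConfig, DrsnModel, predict_force, save_drsn, train_drsn
from .features import FeatureSpec, featurize
from .kpca import kpca_fit, kpca_project, pca_fit, pca_project, contribution_rates
from .metrics import add_noise_snr, metrics_suite
from .miv import MivReport, muscle_contribution_table, muscle_miv
from .synth import Recording, SynthConfig, generate_recording, generate_task_suite
from .windows import WindowSpec, WindowedDataset, build_windows

logger = logging.getLogger("emgforce")

__all__ = ["ExperimentConfig", "chronological_split", "run_experiment",
           "compare_muscles", "simulate", "config_from_yaml", "config_to_yaml"]

REDUCTIONS = ("none", "pca", "kpca", "features")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs; ``seed`` overrides nested seeds."""

    synth: SynthConfig = SynthConfig()
    input_path: str | None = None           # CSV recording; None = synthesize
    window: WindowSpec = WindowSpec(channel_mode="stacked")
    reduction: str = "kpca"
    xi_threshold: float = 0.85              # component-selection cutoff
    gamma: float | None = None              # None = median heuristic
    features: FeatureSpec = FeatureSpec()
    drsn: DrsnConfig = DrsnConfig()
    miv_perturbation: float = 0.10
    miv_cutoff: float = 0.90
    noise_snr_db: float | None = None       # extra acquisition noise on raw sEMG
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")
        if abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) <= 0:
            raise ValueError("split fractions must be positive and sum to 1")


def config_to_yaml(cfg: ExperimentConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def config_from_yaml(text: str) -> ExperimentConfig:
    d = yaml.safe_load(text) or {}
    return _config_from_dict(d)


def _config_from_dict(d: dict) -> ExperimentConfig:
    kw = dict(d)
    if "synth" in kw:
        kw["synth"] = eio.synth_config_from_dict(kw["synth"])
    if "window" in kw:
        kw["window"] = WindowSpec(**kw["window"])
    if "features" in kw:
        fkw = dict(kw["features"])
        if isinstance(fkw.get("features"), list):
            fkw["features"] = tuple(fkw["features"])
        kw["features"] = FeatureSpec(**fkw)
    if "drsn" in kw:
        dkw = dict(kw["drsn"])
        if isinstance(dkw.get("channels"), list):
            dkw["channels"] = tuple(dkw["channels"])
        kw["drsn"] = DrsnConfig(**dkw)
    if isinstance(kw.get("split"), list):
        kw["split"] = tuple(kw["split"])
    return ExperimentConfig(**kw)


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(config_to_yaml(cfg).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# splitting and reduction

def chronological_split(dataset: WindowedDataset,
                        fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
                        ) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Chronological train/val/test split with a stride-aware guard gap.

    Windows ``i`` and ``j`` share samples iff ``|i-j| * stride < window_len``;
    that many boundary windows are dropped between consecutive splits so no
    sample appears on both sides.
    """
    n = len(dataset)
    gap = math.ceil(dataset.window_len / dataset.stride) - 1
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    i1, i2 = n_train, n_train + gap
    i3, i4 = i2 + n_val, i2 + n_val + gap
    if i4 >= n:
        raise ValueError(f"dataset of {n} windows too small for split+gap")
    return (dataset.subset(np.arange(0, i1)),
            dataset.subset(np.arange(i2, i3)),
            dataset.subset(np.arange(i4, n)))


@dataclass
class Reducer:
    """Train-set-fitted window transform (identity, PCA, KPCA or features)."""

    kind: str
    transform: Callable[[WindowedDataset], WindowedDataset]
    n_components: int | None = None
    contributions: np.ndarray | None = None


def fit_reducer(train: WindowedDataset, cfg: ExperimentConfig) -> Reducer:
    if cfg.reduction == "none":
        return Reducer(kind="none", transform=lambda ds: ds)
    if cfg.reduction == "features":
        spec = cfg.features
        return Reducer(kind="features", transform=lambda ds: featurize(ds, spec))
    if cfg.reduction == "pca":
        full = pca_fit(train.X, k=min(train.X.shape))
        cont = contribution_rates(full.eigenvalues)
        k = int(np.searchsorted(np.cumsum(cont), cfg.xi_threshold - 1e-12) + 1)
        model = pca_fit(train.X, k=k)

        def tf(ds: WindowedDataset) -> WindowedDataset:
            return WindowedDataset(pca_project(model, ds.X), ds.y.copy(),
                                   ds.window_len, ds.stride, 1, ds.labels, "pca")
        return Reducer(kind="pca", transform=tf, n_components=k,
                       contributions=cont)
    model = kpca_fit(train.X, gamma=cfg.gamma, xi_threshold=cfg.xi_threshold)

    def tf(ds: WindowedDataset) -> WindowedDataset:
        return WindowedDataset(kpca_project(model, ds.X), ds.y.copy(),
                               ds.window_len, ds.stride, 1, ds.labels, "kpca")
    return Reducer(kind="kpca", transform=tf, n_components=model.P,
                   contributions=model.contributions)


# ---------------------------------------------------------------------------
# commands

def _prepare_recording(cfg: ExperimentConfig) -> Recording:
    if cfg.input_path is not None:
        rec = eio.read_recording(cfg.input_path)
    else:
        rec = generate_recording(replace(cfg.synth, seed=cfg.seed))
    if cfg.noise_snr_db is not None:
        noisy = np.column_stack([
            add_noise_snr(rec.signals[:, c], cfg.noise_snr_db,
                          seed=cfg.seed * 131 + 17 + c)
            for c in range(rec.n_channels)])
        rec = Recording(signals=noisy, force=rec.force, fs=rec.fs,
                        labels=rec.labels, truth=rec.truth)
    return rec


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_results(path: Path, results: dict) -> None:
    """Flat, diffable one-metric-per-line text file with sorted keys."""
    lines = [f"{k}: {_fmt(results[k])}" for k in sorted(results)]
    path.write_text("\n".join(lines) + "\n")


def simulate(cfg: ExperimentConfig, outdir, suite: bool = False) -> list[Path]:
    """Write synthetic recording CSV(s) + provenance sidecars to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = replace(cfg.synth, seed=cfg.seed)
    logger.info("simulate: seed=%d config=%s", cfg.seed, config_hash(cfg))
    if suite:
        recs = generate_task_suite(synth)
        return [eio.write_recording(r, outdir / f"{task}.csv")
                for task, r in recs.items()]
    rec = generate_recording(synth)
    return [eio.write_recording(rec, outdir / f"{synth.task}.csv")]


def run_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """Full pipeline on one recording; writes results.txt, model and MIV report.

    Returns the flat results dict that is also written to disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run: seed=%d config=%s", cfg.seed, config_hash(cfg))

    rec = _prepare_recording(cfg)
    raw = build_windows(rec, cfg.window)
    tr_raw, va_raw, te_raw = chronological_split(raw, cfg.split)
    reducer = fit_reducer(tr_raw, cfg)
    tr, va, te = (reducer.transform(d) for d in (tr_raw, va_raw, te_raw))

    drsn_cfg = replace(cfg.drsn, seed=cfg.seed)
    model = train_drsn(drsn_cfg, tr, va)
    pred = predict_force(model, te)
    m = metrics_suite(te.y, pred)

    # muscle-level MIV on the held-out windows: perturb raw channels, re-reduce
    def make_ds(r: Recording) -> WindowedDataset:
        ds = build_windows(r, cfg.window)
        _, _, te_r = chronological_split(ds, cfg.split)
        return reducer.transform(te_r)

    report = muscle_miv(lambda ds: predict_force(model, ds), rec, make_ds,
                        cfg.miv_perturbation, cfg.miv_cutoff)

    results = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_windows": len(raw),
        "n_train": len(tr), "n_val": len(va), "n_test": len(te),
        "reduction": cfg.reduction,
        "n_components": reducer.n_components if reducer.n_components else 0,
        "test_mse": m.mse, "test_rms": m.rms, "test_mave": m.mave,
        "test_rho_pct": m.rho,
        "miv_ranking": ",".join(report.names[i] for i in report.ranking),
        "miv_selected": ",".join(report.names[i] for i in report.selected),
    }
    for i, name in enumerate(report.names):
        results[f"miv_{name}"] = float(report.miv[i])
        results[f"contribution_{name}"] = float(report.abs_normalized[i])

    write_results(outdir / "results.txt", results)
    save_drsn(model, outdir / "model.npz")
    report.to_frame().to_csv(outdir / "miv.csv", index=False)
    pd.DataFrame({"measured": te.y, "predicted": pred}).to_csv(
        outdir / "predictions.csv", index=False)
    return results


def compare_muscles(cfg: ExperimentConfig, outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-task single-muscle vs combined-muscle comparison.

    For each of the four tasks, trains one model per single channel plus one
    on all channels; writes the task x input-set test-MSE table and the
    task x muscle MIV contribution heatmap (rows normalized to sum 1).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("compare-muscles: seed=%d config=%s", cfg.seed, config_hash(cfg))
    synth = replace(cfg.synth, seed=cfg.seed)
    suite = generate_task_suite(synth)
    labels = synth.channel_labels
    mse_rows: dict[str, dict[str, float]] = {}
    reports: dict[str, MivReport] = {}

    for task, rec in suite.items():
        row: dict[str, float] = {}
        for c, label in enumerate(labels):
            spec = replace(cfg.window, channel_mode="per_channel", channel=c)
            row[label] = _train_and_score(cfg, rec, spec)[0].mse
        spec = replace(cfg.window, channel_mode="stacked")
        m, model, reducer = _train_and_score(cfg, rec, spec, keep=True)
        row["combined"] = m.mse

        def make_ds(r: Recording, _spec=spec, _red=reducer) -> WindowedDataset:
            ds = build_windows(r, _spec)
            _, _, te_r = chronological_split(ds, cfg.split)
            return _red.transform(te_r)

        reports[task] = muscle_miv(lambda ds: predict_force(model, ds), rec,
                                   make_ds, cfg.miv_perturbation, cfg.miv_cutoff)
        mse_rows[task] = row

    mse_df = pd.DataFrame.from_dict(mse_rows, orient="index",
                                    columns=list(labels) + ["combined"])
    heat_df = muscle_contribution_table(reports)
    mse_df.to_csv(outdir / "mse_table.csv")
    heat_df.to_csv(outdir / "miv_heatmap.csv")
    return mse_df, heat_df


def _train_and_score(cfg: ExperimentConfig, rec: Recording, spec: WindowSpec,
                     keep: bool = False):
    raw = build_windows(rec, spec)
    tr_raw, va_raw, te_raw = chronological_split(raw, cfg.split)
    reducer = fit_reducer(tr_raw, cfg)
    tr, va, te = (reducer.transform(d) for d in (tr_raw, va_raw, te_raw))
    model = train_drsn(replace(cfg.drsn, seed=cfg.seed), tr, va)
    m = metrics_suite(te.y, predict_force(model, te))
    if keep:
        return m, model, reducer
    return m, None, None
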