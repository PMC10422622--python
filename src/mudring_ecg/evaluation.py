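"""One-vs-rest classification metrics and the end-to-end pipeline.

Every class is scored against the rest of the confusion matrix:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n,
precision TP/(TP+FP) and F-score 2·prec·sens/(prec+sens), all in percent,
plus an unweighted macro average row.  Ratios with a zero denominator are
reported as 0 with a logged note (small runs can leave a class unpredicted).

``run_pipeline`` wires the whole tool together: synthesize a labelled ECG
collection, drop NULL records, resample to a common rate, normalise,
extract the ten-feature vectors, tune the stacked-autoencoder classifier
with the mud-ring optimizer on a stratified train/validation split, and
score the refitted model on the held-out test split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import features as _features
from . import mroa as _mroa
from . import saetm as _saetm
from . import synthetic_ecg as _syn

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("Sensy", "Specy", "Accuy", "Precn", "FScore")


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts; TP+FP+FN+TN = n for every class."""

    counts: dict  # class -> {"TP": int, "FP": int, "FN": int, "TN": int}
    n: int


def one_vs_rest_counts(y_true, y_pred, class_set) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    classes = list(class_set)
    known = set(classes)
    for v in np.concatenate([y_true, y_pred]).tolist():
        if v not in known:
            raise ValueError(f"unknown label {v!r}")
    n = y_true.size
    counts = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        counts[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": n - tp - fp - fn}
    return ConfusionCounts(counts=counts, n=n)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; reporting 0", what)
        return 0.0
    return num / den


def metrics_table(y_true, y_pred, class_set) -> pd.DataFrame:
    """Per-class and macro metrics in percent, Table-style layout.

    Rows are the classes in the given order plus an ``Average`` row that is
    the unweighted arithmetic mean of the per-class rows.
    """
    if np.asarray(y_true).size == 0:
        raise ValueError("empty input")
    cc = one_vs_rest_counts(y_true, y_pred, class_set)
    rows = {}
    for c, k in cc.counts.items():
        sens = _ratio(k["TP"], k["TP"] + k["FN"], f"sensitivity[{c}]")
        spec = _ratio(k["TN"], k["TN"] + k["FP"], f"specificity[{c}]")
        acc = (k["TP"] + k["TN"]) / cc.n
        prec = _ratio(k["TP"], k["TP"] + k["FP"], f"precision[{c}]")
        f1 = _ratio(2 * prec * sens, prec + sens, f"F-score[{c}]")
        rows[c] = [100 * sens, 100 * spec, 100 * acc, 100 * prec, 100 * f1]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_COLUMNS))
    df.loc["Average"] = df.mean(axis=0)
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run (YAML-serialisable)."""

    seed: int = 0
    # [generate]
    n_records: int = 600
    n_null: int = 6
    fs_mix: float = 0.5
    duration_s: float = 10.0
    lead_count: int = 1
    noise_sd: float = 0.05
    target_fs: float = 100.0
    # [features]
    band_edges: tuple = _features.DEFAULT_BAND_EDGES
    kmax: int = 10
    m: int = 2
    r_factor: float = 0.2
    embed_dim: int = 2
    # [mroa]
    pop: int = 6
    iters: int = 5
    # [saetm]
    epochs: int = 50
    batch_size: int = 5
    # [evaluate]
    val_frac: float = 0.15
    test_frac: float = 0.15

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band_edges"] = list(d["band_edges"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band_edges" in d:
            d["band_edges"] = tuple(d["band_edges"])
        return cls(**d)


def _split(X, y, config: PipelineConfig):
    holdout = config.val_frac + config.test_frac
    X_tr, X_rest, y_tr, y_rest = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=config.seed)
    X_val, X_te, y_val, y_te = train_test_split(
        X_rest, y_rest, test_size=config.test_frac / holdout, stratify=y_rest,
        random_state=config.seed)
    return (X_tr, y_tr), (X_val, y_val), (X_te, y_te)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute generate → filter → resample → normalize → features → split →
    tune → fit → score; returns the artefacts and writes them if ``outdir``
    is given.  Fully reproducible from ``config.seed``."""
    stage = "generate"
    try:
        dataset = _syn.generate_dataset(
            n_records=config.n_records, n_null=config.n_null, fs_mix=config.fs_mix,
            seed=config.seed, duration_s=config.duration_s,
            lead_count=config.lead_count, noise_sd=config.noise_sd)

        stage = "preprocess"
        filtered = _syn.remove_null(dataset)
        processed = _syn.Dataset(
            records=[_syn.normalize(_syn.resample(r, config.target_fs))
                     for r in filtered],
            seed=dataset.seed, params=dict(dataset.params))

        stage = "features"
        fmat = _features.feature_matrix(
            processed, band_edges=config.band_edges, kmax=config.kmax,
            m=config.m, r_factor=config.r_factor, embed_dim=config.embed_dim)
        feat_cols = [c for c in fmat.columns if c not in ("id", "label")]
        X = fmat[feat_cols].to_numpy(dtype=float)
        y = fmat["label"].to_numpy()

        stage = "split"
        (X_tr, y_tr), (X_val, y_val), (X_te, y_te) = _split(X, y, config)

        stage = "tune"
        classes = sorted(set(y.tolist()))
        train_config = _saetm.TrainConfig(epochs=config.epochs,
                                          batch_size=config.batch_size,
                                          seed=config.seed)
        mroa_config = _mroa.MROAConfig(n_agents=config.pop, max_iter=config.iters,
                                       seed=config.seed)
        best_hp, stack, opt_result = _mroa.tune_saetm(
            X_tr, y_tr, X_val, y_val, mroa_config=mroa_config,
            train_config=train_config, classes=classes)

        stage = "evaluate"
        y_pred = _saetm.predict(stack, X_te)
        table = metrics_table(y_te, y_pred, classes).round(2)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    artifacts = {
        "config": config,
        "dataset": dataset,
        "features": fmat,
        "best_hyperparameters": best_hp,
        "tuning_history": opt_result.history,
        "tuned_validation_error": opt_result.best_fitness,
        "splits": {"train": (X_tr, y_tr), "val": (X_val, y_val),
                   "test": (X_te, y_te)},
        "stack": stack,
        "metrics": table,
        "test_labels": y_te,
        "test_predictions": y_pred,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        _syn.save_dataset(dataset, outdir / "dataset.csv")
        _features.save_features(fmat, outdir / "features.csv")
        pd.DataFrame({"iteration": np.arange(len(opt_result.history)),
                      "best_error_pct": opt_result.history}
                     ).to_csv(outdir / "tuning_log.csv", index=False)
        (outdir / "best_hyperparameters.json").write_text(
            json.dumps(best_hp, indent=2))
        _saetm.save_stack(stack, outdir / "model.json")
        table.to_csv(outdir / "metrics.csv", float_format="%.2f")
    return artifacts
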