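"""Experiment matrix, f1 summaries, and the performance-vs-shift trend.

A *task* is one (setting, train, test) split.  Each model family is
trained on each task once per (learning rate, batch size) combination of
the 3 x 3 grid, and the task's f1 is reported as mean +/- sd over those
nine runs.  Setting-level summaries aggregate per-dataset task means
into a results table with an Avg. OOD column (the three OOD settings
averaged per dataset first).  Finally, the mean f1 per task is regressed
on the natural log of that task's distance ratio; a negative slope means
performance decays as the test distribution drifts from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.metrics import f1_score

from . import models as M
from .features import (RepresentationMatrix, apply_scaler, build_registry,
                       extract_features, fit_scaler)
from .harmonize import WindowSet
from .similarity import RatioEstimate, distance_ratio
from .splits import SETTINGS, TaskSpec

logger = logging.getLogger(__name__)


def f1(y_true, y_pred, average: str = "weighted") -> float:
    """Per-class f1 combined by macro or (class-frequency) weighted average.

    Classes absent from both truth and prediction do not participate.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if average not in ("macro", "weighted"):
        raise ValueError(f"unsupported average {average!r}")
    labels = sorted(set(y_true) | set(y_pred))
    return float(f1_score(y_true, y_pred, labels=labels, average=average,
                          zero_division=0))


# ---------------------------------------------------------------------------
# Per-task data preparation (split -> scale -> normalize, without leakage)

@dataclass
class TaskData:
    """Train/test arrays for one task, with all scalers fitted on train."""

    train: dict
    test: dict
    train_labels: np.ndarray
    test_labels: np.ndarray


def prepare_task_data(task: TaskSpec, windowset: WindowSet,
                      features: RepresentationMatrix,
                      feature_ids: np.ndarray | None = None,
                      per_channel_window_norm: bool = False) -> TaskData:
    """Assemble model inputs for one task.

    Handcrafted features are Z-scored with statistics of the task's
    train rows only; windows are normalized by the train-window mean/sd
    (one global pair by default, per channel on request).  ``features``
    rows must align with ``windowset`` rows.
    """
    ids = feature_ids if feature_ids is not None else windowset.ids
    pos = {wid: i for i, wid in enumerate(ids)}
    tr = np.array([pos[w] for w in task.train_ids])
    te = np.array([pos[w] for w in task.test_ids])

    train_rep = RepresentationMatrix(features.values[tr], features.dim_names,
                                     features.source)
    scaler = fit_scaler(train_rep)
    train_feats = apply_scaler(scaler, train_rep).values
    test_feats = apply_scaler(
        scaler, RepresentationMatrix(features.values[te], features.dim_names,
                                     features.source)).values

    train_win = np.transpose(windowset.values[tr], (0, 2, 1))  # N x 4 x 250
    test_win = np.transpose(windowset.values[te], (0, 2, 1))
    norm = M.fit_window_norm(train_win, per_channel=per_channel_window_norm)
    return TaskData(
        train={"windows": M.apply_window_norm(norm, train_win),
               "features": train_feats, "labels": windowset.labels[tr]},
        test={"windows": M.apply_window_norm(norm, test_win),
              "features": test_feats, "labels": windowset.labels[te]},
        train_labels=windowset.labels[tr],
        test_labels=windowset.labels[te],
    )


# ---------------------------------------------------------------------------
# Running tasks

@dataclass
class TaskResult:
    family: str
    task: TaskSpec
    f1_values: tuple[float, ...]
    incomplete: bool = False
    trained: list = field(default_factory=list, repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.f1_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.f1_values))


def run_task(task: TaskSpec, family: str, data: TaskData, base_seed: int = 0,
             configs: list[M.TrainConfig] | None = None,
             average: str = "weighted", pool_stride: int | None = 1,
             keep_models: bool = False) -> TaskResult:
    """Train one family on one task over the hyperparameter grid.

    Defaults to the full 9-run (learning rate, batch size) grid; a
    reduced ``configs`` list supports scaled-down studies.  A failed run
    is recorded and excluded, flagging the result incomplete.
    """
    configs = configs if configs is not None else M.grid_configs(base_seed)
    scores, kept, incomplete = [], [], False
    for cfg in configs:
        try:
            net = M.build_model(M.default_spec(family, pool_stride=pool_stride),
                                seed=cfg.seed)
            trained = M.train(net, data.train, cfg)
            pred = M.predict(trained, data.test)
            scores.append(f1(data.test_labels, pred, average=average))
            if keep_models:
                kept.append(trained)
        except Exception:
            logger.exception("run failed: family=%s lr=%g batch=%d",
                             family, cfg.learning_rate, cfg.batch_size)
            incomplete = True
    if not scores:
        raise RuntimeError(f"every run failed for family {family}")
    if incomplete:
        logger.warning("TaskResult for %s/%s is incomplete (%d of %d runs)",
                       family, task.setting, len(scores), len(configs))
    return TaskResult(family, task, tuple(scores), incomplete, kept)


def summarize(results: list[TaskResult]) -> pd.DataFrame:
    """Table-style summary: rows = families, columns = settings + Avg. OOD.

    Cells are (mean, sd) over datasets of the per-dataset task means;
    OOD-SD tasks are first averaged per target dataset over their source
    datasets.  Missing (family, setting) cells are flagged and left NaN.
    """
    rows = []
    for r in results:
        rows.append({"family": r.family, "setting": r.task.setting,
                     "target": r.task.target_dataset, "f1": r.mean,
                     "incomplete": r.incomplete})
    df = pd.DataFrame(rows)
    if df["incomplete"].any():
        logger.warning("summary includes incomplete task results")
    families = sorted(set(df["family"]))
    table: dict[str, dict] = {}
    for fam in families:
        sub = df[df["family"] == fam]
        cells = {}
        for setting in SETTINGS:
            ss = sub[sub["setting"] == setting]
            if not len(ss):
                logger.warning("missing cell: %s / %s", fam, setting)
                cells[setting] = (np.nan, np.nan)
                continue
            per_ds = ss.groupby("target")["f1"].mean()
            cells[setting] = (float(per_ds.mean()), float(per_ds.std(ddof=0)))
        ood = sub[sub["setting"] != "ID"]
        per_ds = (ood.groupby(["target", "setting"])["f1"].mean()
                     .groupby("target").mean())
        cells["Avg. OOD"] = (float(per_ds.mean()), float(per_ds.std(ddof=0)))
        table[fam] = cells
    return pd.DataFrame(table).T


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line of mean f1 on ln(distance ratio)."""

    slope: float
    intercept: float
    points: tuple  # of (log_ratio, f1_mean, f1_sd)


def trend(results: list[TaskResult],
          ratios: dict[TaskSpec, RatioEstimate]) -> dict[str, TrendFit]:
    """Per-family regression of task-mean f1 against ln(distance ratio)."""
    fits = {}
    for fam in sorted({r.family for r in results}):
        pts = [(np.log(ratios[r.task].mean), r.mean, r.sd)
               for r in results if r.family == fam and r.task in ratios]
        if len(pts) < 3:
            raise ValueError(f"need at least 3 points to fit a trend for {fam}")
        x, y, _ = map(np.array, zip(*pts))
        if np.allclose(y, y[0]):
            fits[fam] = TrendFit(0.0, float(y[0]), tuple(pts))
            continue
        fit = linregress(x, y)
        fits[fam] = TrendFit(float(fit.slope), float(fit.intercept), tuple(pts))
    return fits


# ---------------------------------------------------------------------------
# End-to-end experiment driver

def compute_task_ratios(tasks: list[TaskSpec], windowset: WindowSet,
                        features: RepresentationMatrix, metric: str = "wasserstein",
                        n_repeats: int = 30, seed: int = 0,
                        ) -> dict[TaskSpec, RatioEstimate]:
    """Distance ratios on (train-scaled) handcrafted features, one per task."""
    out = {}
    pos = {wid: i for i, wid in enumerate(windowset.ids)}
    for i, task in enumerate(tasks):
        tr = np.array([pos[w] for w in task.train_ids])
        te = np.array([pos[w] for w in task.test_ids])
        train_rep = RepresentationMatrix(features.values[tr], features.dim_names,
                                         features.source)
        scaler = fit_scaler(train_rep)
        X = apply_scaler(scaler, train_rep).values
        Y = apply_scaler(
            scaler, RepresentationMatrix(features.values[te], features.dim_names,
                                         features.source)).values
        out[task] = distance_ratio(metric, X, Y, n_repeats=n_repeats,
                                   seed=seed + i)
    return out


def reversal_study(seed: int, families=("LR", "CNN-base"), n_runs: int = 3,
                   n_subjects: int = 4, activity_seconds: float = 80.0,
                   sigma_dataset: float = 0.9, sigma_subject: float = 0.15,
                   artifact_rate: float = 0.02, max_epochs: int = 30,
                   patience: int = 30, learning_rate: float = 0.003,
                   batch_size: int = 64, ratio_metric: str = "wasserstein",
                   ratio_repeats: int = 20):
    """Scaled-down in- vs out-of-distribution comparison of two families.

    Runs the full four-setting task matrix on a small benchmark with a
    strong dataset-level shift, using a reduced single-point
    hyperparameter grid and conventional pooling stride.  Mirroring the
    full protocol's per-task averaging over grid runs, each task's f1 is
    the mean over ``n_runs`` training runs with seeds seed, seed+1, ...
    on the one seeded corpus.  Returns ``(summary, fits)``: the
    per-family setting table and the f1-vs-ln(ratio) trend per family.
    """
    from .splits import make_all_tasks
    from .synthgen import BenchmarkConfig, make_benchmark
    from .harmonize import harmonize_corpus

    cfg = BenchmarkConfig(n_subjects=n_subjects,
                          activity_seconds=activity_seconds,
                          sigma_dataset=sigma_dataset,
                          sigma_subject=sigma_subject,
                          artifact_rate=artifact_rate)
    ws = harmonize_corpus(make_benchmark(cfg, seed=seed))
    tasks = make_all_tasks(ws, seed=seed)
    feats = extract_features(ws, build_registry())
    flat_tasks = [t for ts in tasks.values() for t in ts]
    ratios = compute_task_ratios(flat_tasks, ws, feats, metric=ratio_metric,
                                 n_repeats=ratio_repeats, seed=seed)
    configs = [M.TrainConfig(learning_rate=learning_rate,
                             batch_size=batch_size, max_epochs=max_epochs,
                             patience=patience, seed=seed + i)
               for i in range(n_runs)]
    results = []
    for task in flat_tasks:
        data = prepare_task_data(task, ws, feats,
                                 per_channel_window_norm=True)
        for family in families:
            results.append(run_task(task, family, data, configs=configs,
                                    pool_stride=None))
    return summarize(results), trend(results, ratios)


def run_experiment(windowset: WindowSet, families, tasks_by_setting: dict,
                   base_seed: int = 0, configs=None, average: str = "weighted",
                   pool_stride: int | None = 1) -> list[TaskResult]:
    """Run the full (families x tasks x grid) matrix on one corpus."""
    feats = extract_features(windowset, build_registry())
    results = []
    all_tasks = [t for ts in tasks_by_setting.values() for t in ts]
    for task in all_tasks:
        data = prepare_task_data(task, windowset, feats)
        for family in families:
            results.append(run_task(task, family, data, base_seed=base_seed,
                                    configs=configs, average=average,
                                    pool_stride=pool_stride))
    return results
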