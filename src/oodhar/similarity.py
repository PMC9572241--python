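"""Quantifying how out-of-distribution a test representation is.

Four set-level statistics are computed between train and test
representation matrices:

- ``euclidean`` / ``cosine``: Euclidean distance / cosine similarity
  between the two column-mean centroids;
- ``wasserstein``: the average over dimensions of the 1-D Wasserstein-1
  distance between the two empirical marginals (closed form on sorted
  samples);
- ``mmd``: the unbiased linear-kernel maximum mean discrepancy,

      MMD(X, Y) = 1/(n(n-1)) sum_{i != j} x_i . x_j
                + 1/(m(m-1)) sum_{i != j} y_i . y_j
                - 2/(nm)     sum_{i, j}   x_i . y_j .

Because the raw metrics live on incomparable scales, shift is reported
as a bootstrap *distance ratio*: the between-set distance over subsets
divided by a within-train baseline distance, both on subsets of size
floor(min(|train|, |test|) / 2) sampled with replacement.  A ratio near
1 means the test set looks like a fresh draw from the training
distribution.

The Degree of Correspondence (DC) is a permutation test for the
hypothesis that two samples share a distribution: the multiset of
pairwise distances within the reference sample T is compared (via the
two-sample Kolmogorov-Smirnov statistic) with the pairwise distances of
T after its nearest neighbors of V are replaced by V; the observed
deviation is ranked against deviations from random re-partitions of the
pooled rows.  Small p-values flag V as out-of-distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import ks_2samp, wasserstein_distance

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "cosine", "wasserstein", "mmd")
#: larger = closer for similarities, farther for distances
METRIC_DIRECTION = {"euclidean": "distance", "cosine": "similarity",
                    "wasserstein": "distance", "mmd": "distance"}

DEGENERACY_EPS = 1e-12
DEFAULT_N_REPEATS = 30
#: pairwise-distance computations subsample inputs beyond this many rows
MAX_PAIRWISE_ROWS = 300


def _values(A) -> np.ndarray:
    return A.values if hasattr(A, "values") else np.asarray(A, dtype=float)


def linear_mmd(X: np.ndarray, Y: np.ndarray) -> float:
    """Unbiased linear-kernel MMD (can be negative under the null)."""
    X, Y = _values(X), _values(Y)
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("unbiased MMD needs at least 2 rows per set")
    sx, sy = X.sum(axis=0), Y.sum(axis=0)
    xx = (sx @ sx - np.einsum("ij,ij->", X, X)) / (n * (n - 1))
    yy = (sy @ sy - np.einsum("ij,ij->", Y, Y)) / (m * (m - 1))
    xy = (sx @ sy) / (n * m)
    return float(xx + yy - 2 * xy)


def mean_wasserstein(X: np.ndarray, Y: np.ndarray) -> float:
    """Average over dimensions of the 1-D Wasserstein-1 distance."""
    X, Y = _values(X), _values(Y)
    return float(np.mean([wasserstein_distance(X[:, j], Y[:, j])
                          for j in range(X.shape[1])]))


def set_distance(metric: str, A, B) -> float:
    """A single set-level statistic between two representation matrices."""
    X, Y = _values(A), _values(B)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("A and B must be 2-D with matching dimensionality")
    if metric == "euclidean":
        return float(np.linalg.norm(X.mean(axis=0) - Y.mean(axis=0)))
    if metric == "cosine":
        a, b = X.mean(axis=0), Y.mean(axis=0)
        den = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / den) if den > 0 else 0.0
    if metric == "wasserstein":
        return mean_wasserstein(X, Y)
    if metric == "mmd":
        return linear_mmd(X, Y)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Bootstrap distance-ratio protocol

@dataclass(frozen=True)
class RatioEstimate:
    metric: str
    mean: float
    sd: float
    n_repeats: int
    subset_size: int


def distance_ratio(metric: str, train_rep, test_rep,
                   n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
                   max_redraws: int = 100) -> RatioEstimate:
    """Mean +/- sd of the between/within distance ratio over bootstrap repeats.

    Each repeat draws, with replacement, a train and a test subset for
    the numerator and two train subsets for the denominator, all of size
    floor(min(|train|, |test|) / 2).  Near-zero denominators are
    rejected and redrawn (logged); if every redraw is degenerate the
    protocol fails.
    """
    X, Y = _values(train_rep), _values(test_rep)
    if min(len(X), len(Y)) < 4:
        raise ValueError("distance_ratio needs at least 4 rows per side")
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    k = min(len(X), len(Y)) // 2
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_repeats):
        tr1 = X[rng.integers(0, len(X), size=k)]
        ts1 = Y[rng.integers(0, len(Y), size=k)]
        num = set_distance(metric, tr1, ts1)
        den = 0.0
        for attempt in range(max_redraws):
            tr2 = X[rng.integers(0, len(X), size=k)]
            tr3 = X[rng.integers(0, len(X), size=k)]
            den = set_distance(metric, tr2, tr3)
            if abs(den) > DEGENERACY_EPS:
                break
            logger.info("degenerate denominator (|%g| <= %g), redrawing",
                        den, DEGENERACY_EPS)
        else:
            raise ValueError("all denominator draws were degenerate")
        ratios.append(num / den)
    ratios = np.asarray(ratios)
    return RatioEstimate(metric, float(ratios.mean()), float(ratios.std()),
                         n_repeats, k)


# ---------------------------------------------------------------------------
# Degree of Correspondence permutation test

@dataclass(frozen=True)
class DCResult:
    p_value: float
    observed_delta: float
    n_permutations: int
    base_distance: str


def _pairwise(X: np.ndarray, metric: str) -> np.ndarray:
    return pdist(X, metric=metric)


def _dc_statistic(T: np.ndarray, V: np.ndarray, metric: str) -> float:
    dT = _pairwise(T, metric)
    # nearest neighbor of each v in T; argmin resolves ties to lowest index
    nn = cdist(V, T, metric=metric).argmin(axis=1)
    keep = np.ones(len(T), dtype=bool)
    keep[nn] = False
    TV = np.concatenate([T[keep], V])
    dTV = _pairwise(TV, metric)
    return float(ks_2samp(dT, dTV, method="asymp").statistic)


def dc(T, V, d: str = "euclidean", B: int = 99, seed: int = 0) -> DCResult:
    """Degree-of-Correspondence permutation p-value.

    The reference sample T must be strictly larger than V.  The observed
    deviation delta between T's pairwise-distance distribution and that
    of T with V's nearest neighbors replaced by V is ranked against B
    random re-partitions of the pooled rows into (|T|, |V|) pieces;
    p = (1 + #{delta' >= delta}) / (B + 1).
    """
    T, V = _values(T), _values(V)
    if len(V) < 2 or len(T) <= len(V):
        raise ValueError("DC requires |T| > |V| >= 2")
    if B < 19:
        raise ValueError("B >= 19 required for p-value resolution")
    if d not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported base distance {d!r}")
    delta = _dc_statistic(T, V, d)
    pool = np.concatenate([T, V])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(len(pool))
        Tp, Vp = pool[perm[:len(T)]], pool[perm[len(T):]]
        if _dc_statistic(Tp, Vp, d) >= delta:
            exceed += 1
    return DCResult((1 + exceed) / (B + 1), delta, B, d)


# ---------------------------------------------------------------------------
# Setting-level shift report

def _subsample_rows(X: np.ndarray, rng: np.random.Generator,
                    cap: int = MAX_PAIRWISE_ROWS) -> np.ndarray:
    if len(X) <= cap:
        return X
    logger.info("subsampling %d rows to %d for pairwise computations", len(X), cap)
    return X[rng.choice(len(X), size=cap, replace=False)]


def shift_report(tasks_by_setting: dict, representations: dict,
                 metrics=METRICS, dc_distances=("euclidean", "cosine"),
                 n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
                 dc_permutations: int = 99) -> pd.DataFrame:
    """Per-setting mean +/- sd of distance ratios and raw DC p-values.

    ``representations`` maps task -> (train RepresentationMatrix, test
    RepresentationMatrix), all from one representation source.  Rows are
    metrics (ratios, plus raw ``dc_<d>`` p-values); columns are settings
    plus an ``Avg. OOD`` column; cells hold (mean, sd) tuples.  The
    Avg. OOD cell averages the three OOD settings per target dataset
    before aggregating across datasets.
    """
    rng = np.random.default_rng(seed)
    rows = list(metrics) + [f"dc_{d}" for d in dc_distances]
    per_task: dict[str, dict] = {}
    for setting, tasks in tasks_by_setting.items():
        if not tasks:
            logger.warning("setting %s has no tasks; omitted", setting)
            continue
        for task in tasks:
            train_rep, test_rep = representations[task]
            Xs = _subsample_rows(_values(train_rep), rng)
            Ys = _subsample_rows(_values(test_rep), rng)
            vals = {}
            for metric in metrics:
                vals[metric] = distance_ratio(
                    metric, Xs, Ys, n_repeats=n_repeats,
                    seed=int(rng.integers(2**31 - 1))).mean
            V = Ys[:len(Xs) - 1] if len(Ys) >= len(Xs) else Ys  # need |T| > |V|
            for dist in dc_distances:
                vals[f"dc_{dist}"] = dc(Xs, V, d=dist, B=dc_permutations,
                                        seed=int(rng.integers(2**31 - 1))).p_value
            per_task[task] = {"setting": setting,
                              "target": task.target_dataset, **vals}
    df = pd.DataFrame.from_dict(per_task, orient="index")
    settings = [s for s in ("ID", "OOD-U", "OOD-MD", "OOD-SD")
                if s in set(df["setting"])]
    table = {}
    for setting in settings:
        sub = df[df["setting"] == setting]
        table[setting] = {r: (sub[r].mean(), sub[r].std(ddof=0)) for r in rows}
    ood = df[df["setting"] != "ID"]
    if len(ood):
        per_ds = (ood.groupby(["target", "setting"])[rows].mean()
                     .groupby("target").mean())
        table["Avg. OOD"] = {r: (per_ds[r].mean(), per_ds[r].std(ddof=0))
                             for r in rows}
    return pd.DataFrame(table).reindex(rows)


def format_shift_report(report: pd.DataFrame) -> str:
    """Render the (mean, sd)-tuple table as 'mean±sd' text cells."""
    out = report.map(lambda cell: f"{cell[0]:.2f}±{cell[1]:.2f}")
    return out.to_string()
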