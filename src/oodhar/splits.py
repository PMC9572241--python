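"""The four domain-generalization settings as explicit train/test tasks.

- ID: within each dataset, a random 30% of windows held out (subjects may
  appear on both sides) — the in-distribution baseline.
- OOD-U: within each dataset, about 30% of *users* held out wholly.
- OOD-MD: one dataset held out for testing, all others train.
- OOD-SD: one source dataset trains, another is held out; all ordered
  pairs are enumerated.

For a fixed target dataset, OOD-MD and OOD-SD reuse that dataset's OOD-U
test windows verbatim, so the three OOD settings are compared on exactly
the same test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .harmonize import WindowSet

SETTINGS = ("ID", "OOD-U", "OOD-MD", "OOD-SD")


class SplitError(ValueError):
    """Raised when a requested split cannot be constructed."""


@dataclass(frozen=True)
class TaskSpec:
    """A (setting, train, test) unit over which models and metrics run."""

    setting: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    source_datasets: frozenset
    target_dataset: str
    seed: int

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise SplitError(f"unknown setting {self.setting!r}")
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise SplitError(f"train/test overlap: {sorted(overlap)[:3]}...")
        if not self.train_ids or not self.test_ids:
            raise SplitError("empty train or test side")
        if self.setting == "OOD-MD" and self.target_dataset in self.source_datasets:
            raise SplitError("OOD-MD target must not be a source dataset")
        if self.setting == "OOD-SD" and (
                len(self.source_datasets) != 1
                or self.target_dataset in self.source_datasets):
            raise SplitError("OOD-SD needs exactly one source != target")

    def to_json(self) -> str:
        return json.dumps({
            "setting": self.setting, "seed": self.seed,
            "source_datasets": sorted(self.source_datasets),
            "target_dataset": self.target_dataset,
            "train_ids": list(self.train_ids), "test_ids": list(self.test_ids),
        }, indent=1)

    @staticmethod
    def from_json(text: str) -> "TaskSpec":
        d = json.loads(text)
        return TaskSpec(d["setting"], tuple(d["train_ids"]), tuple(d["test_ids"]),
                        frozenset(d["source_datasets"]), d["target_dataset"], d["seed"])


def _one_dataset(windowset: WindowSet) -> str:
    datasets = set(windowset.datasets)
    if len(datasets) != 1:
        raise SplitError(f"expected a single-dataset WindowSet, got {sorted(datasets)}")
    return datasets.pop()


def split_id(dataset_windows: WindowSet, test_fraction: float = 0.3,
             seed: int = 0) -> TaskSpec:
    """Random window-level held-out fraction within one dataset."""
    ds = _one_dataset(dataset_windows)
    n = len(dataset_windows)
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise SplitError(f"degenerate ID split: {n_test} of {n} windows in test")
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return TaskSpec("ID", tuple(dataset_windows.ids[~mask]),
                    tuple(dataset_windows.ids[mask]),
                    frozenset([ds]), ds, seed)


def split_ood_u(dataset_windows: WindowSet, user_fraction: float = 0.3,
                seed: int = 0) -> TaskSpec:
    """Hold out about 30% of the subjects wholly (at least one per side)."""
    ds = _one_dataset(dataset_windows)
    subjects = sorted(set(dataset_windows.subjects))
    if len(subjects) < 2:
        raise SplitError("leave-user-out needs at least 2 subjects")
    n_test = min(max(1, int(round(user_fraction * len(subjects)))), len(subjects) - 1)
    rng = np.random.default_rng(seed)
    test_subjects = set(rng.choice(subjects, size=n_test, replace=False))
    mask = np.array([s in test_subjects for s in dataset_windows.subjects])
    return TaskSpec("OOD-U", tuple(dataset_windows.ids[~mask]),
                    tuple(dataset_windows.ids[mask]),
                    frozenset([ds]), ds, seed)


def split_ood_md(all_windows: WindowSet, held_out_dataset: str,
                 ood_u_tasks: dict[str, TaskSpec]) -> TaskSpec:
    """All other datasets train; test is the held-out dataset's OOD-U test set."""
    datasets = set(all_windows.datasets)
    if len(datasets) < 2:
        raise SplitError("OOD-MD needs at least 2 datasets")
    if held_out_dataset not in ood_u_tasks:
        raise SplitError(f"no OOD-U task for {held_out_dataset!r}")
    sources = datasets - {held_out_dataset}
    train_mask = np.array([d in sources for d in all_windows.datasets])
    ood_u = ood_u_tasks[held_out_dataset]
    return TaskSpec("OOD-MD", tuple(all_windows.ids[train_mask]),
                    ood_u.test_ids, frozenset(sources), held_out_dataset,
                    ood_u.seed)


def split_ood_sd(all_windows: WindowSet, source_dataset: str,
                 target_dataset: str, ood_u_tasks: dict[str, TaskSpec]) -> TaskSpec:
    """One source dataset trains; test is the target's OOD-U test set."""
    if source_dataset == target_dataset:
        raise SplitError("OOD-SD source and target must differ")
    if target_dataset not in ood_u_tasks:
        raise SplitError(f"no OOD-U task for {target_dataset!r}")
    train_mask = np.array([d == source_dataset for d in all_windows.datasets])
    if not train_mask.any():
        raise SplitError(f"source dataset {source_dataset!r} has no windows")
    ood_u = ood_u_tasks[target_dataset]
    return TaskSpec("OOD-SD", tuple(all_windows.ids[train_mask]),
                    ood_u.test_ids, frozenset([source_dataset]), target_dataset,
                    ood_u.seed)


def enumerate_ood_sd(all_windows: WindowSet,
                     ood_u_tasks: dict[str, TaskSpec]) -> list[TaskSpec]:
    """All ordered (source, target) pairs: N datasets -> N(N-1) tasks."""
    datasets = sorted(set(all_windows.datasets))
    return [split_ood_sd(all_windows, s, t, ood_u_tasks)
            for s in datasets for t in datasets if s != t]


def make_all_tasks(all_windows: WindowSet, test_fraction: float = 0.3,
                   seed: int = 0) -> dict[str, list[TaskSpec]]:
    """Construct every task of all four settings over a multi-dataset corpus.

    Per-dataset seeds are derived deterministically from ``seed``; the
    OOD-U test sets are built first and shared by OOD-MD/OOD-SD.
    """
    datasets = sorted(set(all_windows.datasets))
    if len(datasets) < 2:
        raise SplitError("the OOD settings need at least 2 datasets")
    tasks: dict[str, list[TaskSpec]] = {s: [] for s in SETTINGS}
    ood_u_by_dataset: dict[str, TaskSpec] = {}
    for k, ds in enumerate(datasets):
        ds_windows = all_windows.select(all_windows.datasets == ds)
        tasks["ID"].append(split_id(ds_windows, test_fraction, seed=seed + 1000 + k))
        ood_u = split_ood_u(ds_windows, test_fraction, seed=seed + 2000 + k)
        ood_u_by_dataset[ds] = ood_u
        tasks["OOD-U"].append(ood_u)
    for ds in datasets:
        tasks["OOD-MD"].append(split_ood_md(all_windows, ds, ood_u_by_dataset))
    tasks["OOD-SD"] = enumerate_ood_sd(all_windows, ood_u_by_dataset)
    return tasks
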