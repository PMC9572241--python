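"""Homogenization of heterogeneous recordings into a windowed corpus.

Recordings arrive at arbitrary native rates with raw label vocabularies.
Harmonization makes them directly comparable: resample to a common
50 Hz, append the orientation-invariant magnitude channel, map labels to
the canonical five-activity nomenclature (up/down stairs merge into one
"stairs" class), then cut 5-second non-overlapping single-label windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthgen import CANONICAL_ACTIVITIES, Recording

TARGET_RATE = 50.0
WINDOW_SECONDS = 5.0
WINDOW_SAMPLES = int(TARGET_RATE * WINDOW_SECONDS)  # 250
N_CHANNELS = 4  # x, y, z, magnitude

#: Marker for raw labels that are removed rather than mapped.
DROP = None

#: Default raw-label mapping: canonical labels pass through, stair
#: variants merge, everything else must be listed explicitly.
DEFAULT_LABEL_MAP = {a: a for a in CANONICAL_ACTIVITIES} | {
    "upstairs": "stairs",
    "downstairs": "stairs",
    "ascending_stairs": "stairs",
    "descending_stairs": "stairs",
}


class LabelMappingError(KeyError):
    """A raw label was encountered that the mapping neither maps nor drops."""


@dataclass
class WindowSet:
    """Fixed-length 4-channel windows with provenance.

    ``values`` is [n_windows x 250 x 4] (channels x, y, z, magnitude);
    ``ids`` are globally unique window identifiers of the form
    ``dataset/subject/serial`` used by the split machinery.
    """

    values: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    datasets: np.ndarray
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (WINDOW_SAMPLES, N_CHANNELS):
            raise ValueError(
                f"values must be [n x {WINDOW_SAMPLES} x {N_CHANNELS}], got {self.values.shape}")
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.datasets = np.asarray(self.datasets, dtype=object)
        if self.ids is None:
            self.ids = np.array(
                [f"{d}/{s}/{i}" for i, (d, s) in enumerate(zip(self.datasets, self.subjects))],
                dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.values)
        for arr, name in ((self.labels, "labels"), (self.subjects, "subjects"),
                          (self.datasets, "datasets"), (self.ids, "ids")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_windows {n}")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate window ids")
        bad = set(self.labels) - set(CANONICAL_ACTIVITIES)
        if bad:
            raise ValueError(f"non-canonical labels in WindowSet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.values)

    def select(self, mask_or_ids) -> "WindowSet":
        """Subset by boolean mask, integer indices, or window ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == object or arr.dtype.kind in "US":
            id_to_pos = {wid: i for i, wid in enumerate(self.ids)}
            idx = np.array([id_to_pos[w] for w in arr], dtype=int)
        else:
            idx = np.flatnonzero(arr) if arr.dtype == bool else arr.astype(int)
        return WindowSet(self.values[idx], self.labels[idx], self.subjects[idx],
                         self.datasets[idx], self.ids[idx])

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        return WindowSet(
            np.concatenate([s.values for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.subjects for s in sets]),
            np.concatenate([s.datasets for s in sets]),
            np.concatenate([s.ids for s in sets]),
        )


def resample(recording: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Resample onto a uniform ``target_rate`` grid.

    Channel values are linearly interpolated on a common time axis;
    per-sample labels are carried by nearest-time assignment.  A
    recording already at the target rate is returned unchanged (copy).
    """
    if recording.rate <= 0:
        raise ValueError("recording rate must be positive")
    if len(recording) == 0:
        raise ValueError("cannot resample an empty recording")
    if recording.rate == target_rate:
        return Recording(recording.samples.copy(), target_rate, recording.labels.copy(),
                         recording.subject_id, recording.dataset_id)
    n_out = int(round(len(recording) * target_rate / recording.rate))
    t_in = np.arange(len(recording)) / recording.rate
    t_out = np.arange(n_out) / target_rate
    out = np.column_stack([
        np.interp(t_out, t_in, recording.samples[:, c])
        for c in range(recording.samples.shape[1])
    ])
    nearest = np.clip(np.round(t_out * recording.rate).astype(int), 0, len(recording) - 1)
    return Recording(out, target_rate, recording.labels[nearest],
                     recording.subject_id, recording.dataset_id)


def magnitude(recording: Recording) -> Recording:
    """Append the per-sample Euclidean norm of the three axes as channel 4.

    The magnitude is invariant to device orientation, so it carries
    information that survives dataset-level rotation shifts.
    """
    if recording.samples.shape[1] != 3:
        raise ValueError("magnitude expects a 3-channel recording")
    mag = np.linalg.norm(recording.samples, axis=1)
    return Recording(np.column_stack([recording.samples, mag]), recording.rate,
                     recording.labels.copy(), recording.subject_id, recording.dataset_id)


def map_labels(recording: Recording, mapping: dict | None = None) -> Recording:
    """Map raw labels to the canonical vocabulary; drop samples mapped to None.

    Every raw label present must appear in the mapping (canonical target
    or explicit drop); an unlisted label raises, naming the offender.
    """
    mapping = DEFAULT_LABEL_MAP if mapping is None else mapping
    present = set(recording.labels)
    missing = present - set(mapping)
    if missing:
        raise LabelMappingError(f"unmapped raw labels: {sorted(missing)}")
    mapped = np.array([mapping[l] for l in recording.labels], dtype=object)
    keep = np.array([m is not DROP for m in mapped], dtype=bool)
    return Recording(recording.samples[keep], recording.rate, mapped[keep],
                     recording.subject_id, recording.dataset_id)


def windowize(recording: Recording, window_seconds: float = WINDOW_SECONDS,
              overlap: float = 0.0, _serial_start: int = 0) -> WindowSet | None:
    """Cut non-overlapping fixed-length single-label windows.

    Windows are cut within each maximal run of one label (restarting at
    every label change), so each emitted window is label-pure and the
    window count equals the sum over single-label segments of
    floor(segment_length / window_samples).  Trailing remainders are
    discarded.  Returns None when no full window fits.
    """
    if overlap != 0.0:
        raise NotImplementedError("only non-overlapping windows are supported")
    if recording.rate != TARGET_RATE or recording.samples.shape[1] != N_CHANNELS:
        raise ValueError("windowize expects a 50 Hz, 4-channel recording")
    w = int(round(window_seconds * recording.rate))
    chunks, labels = [], []
    if len(recording):
        change = np.flatnonzero(recording.labels[1:] != recording.labels[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(recording)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n_win = (hi - lo) // w
            for k in range(n_win):
                chunks.append(recording.samples[lo + k * w: lo + (k + 1) * w])
                labels.append(recording.labels[lo])
    if not chunks:
        return None
    n = len(chunks)
    ids = np.array([f"{recording.dataset_id}/{recording.subject_id}/{_serial_start + k}"
                    for k in range(n)], dtype=object)
    return WindowSet(np.stack(chunks), np.asarray(labels, dtype=object),
                     np.full(n, recording.subject_id, dtype=object),
                     np.full(n, recording.dataset_id, dtype=object), ids)


def subsample(windowset: WindowSet, fraction: float, seed: int) -> WindowSet:
    """Uniform random sample without replacement of round(fraction * n) windows."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return windowset
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(windowset)))
    idx = np.sort(rng.choice(len(windowset), size=k, replace=False))
    return windowset.select(idx)


def harmonize_corpus(corpus: dict[str, list[Recording]],
                     label_mapping: dict | None = None,
                     subsample_fractions: dict[str, float] | None = None,
                     seed: int = 0) -> WindowSet:
    """Full homogenization of a multi-dataset corpus into one WindowSet.

    Per recording: resample to 50 Hz, append magnitude, map labels, cut
    windows.  ``subsample_fractions`` optionally thins a dataset's
    windows (the convention used for corpora that would otherwise
    dominate the pool).
    """
    per_dataset: dict[str, list[WindowSet]] = {}
    serials: dict[tuple[str, str], int] = {}
    for ds_name, recs in corpus.items():
        sets = []
        for rec in recs:
            r = resample(rec)
            if r.samples.shape[1] == 3:
                r = magnitude(r)
            r = map_labels(r, label_mapping)
            key = (r.dataset_id, r.subject_id)
            ws = windowize(r, _serial_start=serials.get(key, 0))
            if ws is not None:
                serials[key] = serials.get(key, 0) + len(ws)
                sets.append(ws)
        if sets:
            per_dataset[ds_name] = sets
    merged = []
    for ds_name, sets in per_dataset.items():
        ws = WindowSet.concatenate(sets)
        if subsample_fractions and ds_name in subsample_fractions:
            ws = subsample(ws, subsample_fractions[ds_name], seed)
        merged.append(ws)
    return WindowSet.concatenate(merged)


# ---------------------------------------------------------------------------
# WindowSet I/O: flat delimited table + index file; lossless to 1e-9.

def write_windowset(windowset: WindowSet, path, index_path=None) -> None:
    """One row per window: dataset subject label then 1000 channel-major values."""
    with open(path, "w") as fh:
        for i in range(len(windowset)):
            flat = windowset.values[i].T.reshape(-1)  # channel-major
            vals = " ".join(f"{v:.17g}" for v in flat)
            fh.write(f"{windowset.datasets[i]} {windowset.subjects[i]} "
                     f"{windowset.labels[i]} {vals}\n")
    index_path = index_path or str(path) + ".index"
    with open(index_path, "w") as fh:
        for i, wid in enumerate(windowset.ids):
            fh.write(f"{i} {wid}\n")


def read_windowset(path, index_path=None) -> WindowSet:
    datasets, subjects, labels, values = [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            datasets.append(parts[0])
            subjects.append(parts[1])
            labels.append(parts[2])
            flat = np.array(parts[3:], dtype=float)
            values.append(flat.reshape(N_CHANNELS, WINDOW_SAMPLES).T)
    index_path = index_path or str(path) + ".index"
    ids = []
    with open(index_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    return WindowSet(np.stack(values), np.asarray(labels, dtype=object),
                     np.asarray(subjects, dtype=object),
                     np.asarray(datasets, dtype=object),
                     np.asarray(ids, dtype=object))
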