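"""Feature-table preparation: balancing, normalization, peak grouping, channel subsets.

Applied in this order, the steps turn a raw feature table into the compact
table the tree is induced on: every class is randomly downsampled to the
minority-class count (decision trees are sensitive to class imbalance), each
attribute column is min-max scaled to [0, 1], and consecutive instances are
grouped into fixed windows whose per-channel maxima become one instance —
each final instance holds the per-electrode peak over roughly one second,
which suppresses the overfitting that instance-level tables produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import FeatureTable

DEFAULT_GROUP_WINDOW = 10

#: Configurable stand-in for a 12-electrode reduced montage; these are
#: electrodes a reduced analysis would plausibly keep (frontal, centro-
#: parietal, parietal, one occipital), not a canonical list.
DEFAULT_CHANNEL_SUBSET_12: tuple[str, ...] = (
    "Fp1", "F3", "F7", "Fz", "FT9", "FT10",
    "CP1", "CP2", "P4", "P7", "Pz", "O1",
)


@dataclass(frozen=True)
class PrepConfig:
    """Parameters of the preparation stage."""

    balance_seed: int = 0
    group_window: int = DEFAULT_GROUP_WINDOW
    channel_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.group_window < 1:
            raise ValueError("group_window must be >= 1")


def balance_classes(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Downsample every class to the minority-class count.

    Sampling is uniform without replacement and seeded. The balanced table is
    emitted in class blocks (classes ordered by first appearance, within-class
    time order preserved) so that each class forms one contiguous run for the
    grouping stage.
    """
    counts = table.class_counts()
    if len(counts) < 2:
        raise ValueError("balancing needs at least two classes")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    labels = table.labels
    blocks = []
    for cls in table.classes:
        idx = np.flatnonzero(labels == cls)
        keep = np.sort(rng.choice(idx, size=m, replace=False))
        blocks.append(table.frame.iloc[keep])
    return FeatureTable(pd.concat(blocks, ignore_index=True))


def normalize_minmax(table: FeatureTable) -> FeatureTable:
    """Min-max scale each attribute column independently to [0, 1].

    Constant columns map to 0; ``Time`` and ``Class`` are untouched.
    """
    if table.n_instances == 0:
        raise ValueError("cannot normalize an empty table")
    frame = table.frame.copy()
    for col in table.channel_names:
        x = frame[col].to_numpy(dtype=float)
        span = x.max() - x.min()
        frame[col] = np.zeros_like(x) if span == 0 else (x - x.min()) / span
    return FeatureTable(frame)


def group_peaks(table: FeatureTable, window: int = DEFAULT_GROUP_WINDOW) -> FeatureTable:
    """Collapse non-overlapping windows of consecutive same-class instances
    into their per-channel maxima.

    Windows never cross a class-run boundary; trailing partial windows are
    dropped. The grouped instance's ``Time`` is the maximum ``Time`` in its
    window and its class is the run's class.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frame = table.frame
    labels = table.labels
    run_id = np.concatenate([[0], np.cumsum(labels[1:] != labels[:-1])])
    rows = []
    for rid in np.unique(run_id):
        run = frame.iloc[np.flatnonzero(run_id == rid)]
        k = len(run) // window
        for w in range(k):
            chunk = run.iloc[w * window : (w + 1) * window]
            row = {"Time": chunk["Time"].max()}
            for col in table.channel_names:
                row[col] = chunk[col].max()
            row["Class"] = chunk["Class"].iloc[0]
            rows.append(row)
    if not rows:
        raise ValueError(
            f"no class run holds at least one full window of {window} instances"
        )
    return FeatureTable(pd.DataFrame(rows, columns=list(frame.columns)))


def select_channels(table: FeatureTable, names: Sequence[str]) -> FeatureTable:
    """Restrict attribute columns to ``names`` (in the given order)."""
    names = list(names)
    if not names:
        raise ValueError("channel selection is empty")
    unknown = [n for n in names if n not in table.channel_names]
    if unknown:
        raise ValueError(f"unknown channel name(s): {', '.join(unknown)}")
    return FeatureTable(table.frame[["Time", *names, "Class"]].copy())


def prepare(table: FeatureTable, config: PrepConfig | None = None) -> FeatureTable:
    """Full preparation: optional channel subset, then balance → normalize → group."""
    config = config or PrepConfig()
    if config.channel_subset is not None:
        table = select_channels(table, config.channel_subset)
    table = balance_classes(table, seed=config.balance_seed)
    table = normalize_minmax(table)
    return group_peaks(table, window=config.group_window)
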