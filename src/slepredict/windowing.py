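"""Sliding-window extraction of labeled (sequence, outcome) instances.

For an observation window of X months (k = X/6 bins) and a prediction
horizon of Y months, one instance is extracted per patient per window
start, stepping one bin at a time along the regularized series.  The label
is 1 iff a hospitalization occurs within Y months after the window end
(half-open interval).  Only windows whose end leaves at least
``label_followup`` months of follow-up are used, so the instance total for
a given k is independent of Y: with six usable bins per patient each
patient contributes 7 - k windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import event_in_interval
from .preprocess import RegularSeries

X_MONTHS_CHOICES = (6, 12, 18, 24, 30, 36)
Y_MONTHS_CHOICES = (3, 6, 9, 12)


@dataclass(frozen=True)
class TaskSpec:
    """An 'observe X months, predict Y months ahead' task."""

    x_months: float
    y_months: float
    bin_months: float = 6.0

    def __post_init__(self) -> None:
        if self.x_months <= 0 or self.y_months <= 0:
            raise ValueError("x_months and y_months must be positive")
        if abs(self.x_months / self.bin_months - round(self.x_months / self.bin_months)) > 1e-9:
            raise ValueError(f"x_months={self.x_months} not a multiple of bin_months")

    @property
    def k(self) -> int:
        """Window length in bins."""
        return int(round(self.x_months / self.bin_months))


@dataclass
class WindowInstance:
    patient_id: str
    start_bin: int
    sequence: np.ndarray  # k x n_features
    demographics: np.ndarray
    label: int


@dataclass
class WindowedDataset:
    task: TaskSpec
    instances: list[WindowInstance] = field(default_factory=list)
    feature_kinds: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.instances)

    @property
    def class1_count(self) -> int:
        return sum(inst.label for inst in self.instances)

    @property
    def labels(self) -> np.ndarray:
        return np.array([inst.label for inst in self.instances], dtype=int)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([inst.patient_id for inst in self.instances])


def usable_bins(series: RegularSeries, label_followup: float = 12.0) -> int:
    """Bins whose window end has at least ``label_followup`` months of follow-up.

    With this definition, labels for every horizon up to ``label_followup``
    are available for every extracted window, so instance totals do not
    vary with Y.
    """
    total_months = series.n_bins * series.bin_months + series.followup_months
    by_followup = int(np.floor((total_months - label_followup) / series.bin_months + 1e-9))
    return max(0, min(series.n_bins, by_followup))


def extract_windows(
    series_list: list[RegularSeries],
    task: TaskSpec,
    label_followup: float = 12.0,
) -> WindowedDataset:
    """Extract all (sequence, label) instances for ``task`` from a cohort."""
    if task.y_months > label_followup:
        raise ValueError(
            f"y_months={task.y_months} exceeds label_followup={label_followup}"
        )
    k = task.k
    ds = WindowedDataset(task=task, feature_kinds=list(series_list[0].feature_kinds))
    skipped = 0
    for s in series_list:
        ub = usable_bins(s, label_followup)
        if ub < k:
            skipped += 1
            continue
        for start in range(0, ub - k + 1):
            end_months = (start + k) * s.bin_months
            label = event_in_interval(s.events, end_months, task.y_months)
            ds.instances.append(
                WindowInstance(
                    patient_id=s.patient_id,
                    start_bin=start,
                    sequence=s.values[start : start + k].copy(),
                    demographics=s.demographics.copy(),
                    label=label,
                )
            )
    if skipped:
        warnings.warn(
            f"{skipped} patients contributed no windows (fewer than k={k} usable bins)"
        )
    return ds


def write_windows(ds: WindowedDataset, outdir, stem: str = "windows") -> None:
    """Write flattened sequences + labels as CSV with a JSON task sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = ds.task.k
    n_feat = ds.instances[0].sequence.shape[1] if ds.instances else 0
    cols = ["patient_id", "start_bin"]
    cols += [f"f{j}_t{t}" for t in range(k) for j in range(n_feat)]
    cols += [f"demo_{i + 1}" for i in range(len(ds.instances[0].demographics))]
    cols += ["label"]
    rows = [
        (inst.patient_id, inst.start_bin, *inst.sequence.ravel(), *inst.demographics, inst.label)
        for inst in ds.instances
    ]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / f"{stem}.csv", index=False)
    sidecar = {
        "x_months": ds.task.x_months,
        "y_months": ds.task.y_months,
        "bin_months": ds.task.bin_months,
        "total": ds.total,
        "class1_count": ds.class1_count,
        "feature_kinds": ds.feature_kinds,
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar))
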