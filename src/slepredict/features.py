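"""Feature construction for the two model families.

The Differential layout flattens each windowed instance into one row:
demographics, the raw clinical features at every step, and lagged
*difference* columns (value at step t minus step t-1) that let non-temporal
learners see disease progression.  The LSTM layout keeps the sequence
structure and appends the static demographics to every time step so all
sequences share one per-step dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windowing import WindowedDataset


@dataclass
class DesignMatrix:
    """Flat feature panel with a tagged column schema."""

    matrix: np.ndarray  # n_instances x p
    schema: list[str]
    schema_tags: list[str]  # 'demographic' | 'raw@{t}' | 'delta@{t}'
    labels: np.ndarray
    patient_ids: np.ndarray
    binary_mask: np.ndarray  # per-column: True if pass-through under scaling

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SequenceTensor:
    """Equal-length sequences: n_instances x k x (n_clinical + n_demographic)."""

    tensor: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    n_demographic: int
    binary_mask: np.ndarray  # per step-feature

    @property
    def k(self) -> int:
        return self.tensor.shape[1]


def _kind_binary_mask(feature_kinds: list[str]) -> np.ndarray:
    return np.array([k == "binary" for k in feature_kinds], dtype=bool)


def build_differential(dataset: WindowedDataset, layout: str = "full") -> DesignMatrix:
    """Build the lagged-difference design matrix from a windowed dataset.

    ``layout='full'`` keeps raw features at every step plus deltas for
    steps 1..k-1: p = 5 + 52*k + 52*(k-1) with the default 52-feature panel.
    ``layout='compact'`` keeps only the first step's raw features plus the
    deltas: p = 5 + 52 + 52*(k-1).
    """
    if layout not in ("full", "compact"):
        raise ValueError(f"unknown layout {layout!r}")
    insts = dataset.instances
    if not insts:
        raise ValueError("empty dataset")
    k, n_feat = insts[0].sequence.shape
    n_demo = len(insts[0].demographics)
    kinds = dataset.feature_kinds or ["continuous"] * n_feat
    feat_binary = _kind_binary_mask(kinds)

    demo = np.vstack([i.demographics for i in insts])
    seq = np.stack([i.sequence for i in insts])  # n x k x f
    raw_steps = range(k) if layout == "full" else range(1)
    blocks = [demo] + [seq[:, t, :] for t in raw_steps]
    blocks += [seq[:, t, :] - seq[:, t - 1, :] for t in range(1, k)]
    matrix = np.hstack(blocks)

    schema: list[str] = [f"demo_{i + 1}" for i in range(n_demo)]
    tags: list[str] = ["demographic"] * n_demo
    # demographics: treat the 0/1 ones as binary by value inspection at use
    # time; conservatively mark all demographics as continuous here and let
    # the scaler's auto-detection refine
    bmask = [False] * n_demo
    for t in raw_steps:
        schema += [f"f{j}_t{t}" for j in range(n_feat)]
        tags += [f"raw@{t}"] * n_feat
        bmask += list(feat_binary)
    for t in range(1, k):
        schema += [f"df{j}_t{t}" for j in range(n_feat)]
        tags += [f"delta@{t}"] * n_feat
        bmask += [False] * n_feat  # deltas of binary flags take values in {-1,0,1}

    return DesignMatrix(
        matrix=matrix,
        schema=schema,
        schema_tags=tags,
        labels=dataset.labels,
        patient_ids=dataset.patient_ids,
        binary_mask=np.asarray(bmask),
    )


def build_lstm_tensor(dataset: WindowedDataset) -> SequenceTensor:
    """Stack windows into an equal-length tensor with demographics per step."""
    insts = dataset.instances
    if not insts:
        raise ValueError("empty dataset")
    k, n_feat = insts[0].sequence.shape
    n_demo = len(insts[0].demographics)
    kinds = dataset.feature_kinds or ["continuous"] * n_feat
    seq = np.stack([i.sequence for i in insts])
    demo = np.vstack([i.demographics for i in insts])
    demo_rep = np.repeat(demo[:, None, :], k, axis=1)
    tensor = np.concatenate([seq, demo_rep], axis=2)
    bmask = np.concatenate([_kind_binary_mask(kinds), np.zeros(n_demo, dtype=bool)])
    return SequenceTensor(
        tensor=tensor,
        labels=dataset.labels,
        patient_ids=dataset.patient_ids,
        n_demographic=n_demo,
        binary_mask=bmask,
    )


class PanelScaler:
    """Z-score continuous columns; pass binary (0/1-valued) columns through.

    Fit on training data only; the same transform is then applied to any
    held-out data.  Zero-variance columns are centred but left unscaled.
    Works on 2-D matrices and on 3-D sequence tensors (scaling is per
    step-feature, shared across time steps).
    """

    def __init__(self, binary_mask: np.ndarray | None = None):
        self.binary_mask = binary_mask

    def _flatten(self, X: np.ndarray) -> np.ndarray:
        return X.reshape(-1, X.shape[-1]) if X.ndim == 3 else X

    def fit(self, X: np.ndarray) -> "PanelScaler":
        flat = self._flatten(np.asarray(X, dtype=float))
        if self.binary_mask is not None:
            binary = np.asarray(self.binary_mask, dtype=bool)
        else:
            # auto-detect: a column whose values are all in {0, 1}
            binary = np.array(
                [np.isin(np.unique(flat[:, j]), (0.0, 1.0)).all() for j in range(flat.shape[1])]
            )
        mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        self.center_ = np.where(binary, 0.0, mean)
        self.scale_ = np.where(binary, 1.0, std)
        self.binary_mask_ = binary
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def standardize(train: np.ndarray, *apply_to: np.ndarray, binary_mask=None):
    """Fit a :class:`PanelScaler` on ``train`` and transform everything.

    Returns ``(train_scaled, *others_scaled, scaler)``.
    """
    scaler = PanelScaler(binary_mask=binary_mask)
    out = [scaler.fit_transform(train)]
    out += [scaler.transform(a) for a in apply_to]
    return (*out, scaler)


def write_sequence_tensor(st: SequenceTensor, path) -> None:
    """Long-format CSV: one row per (instance, step, feature) value."""
    n, k, d = st.tensor.shape
    idx = np.indices((n, k, d)).reshape(3, -1)
    df = pd.DataFrame(
        {
            "instance": idx[0],
            "step": idx[1],
            "feature": idx[2],
            "value": st.tensor.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_sequence_tensor(path) -> np.ndarray:
    df = pd.read_csv(path)
    n = df["instance"].max() + 1
    k = df["step"].max() + 1
    d = df["feature"].max() + 1
    tensor = np.empty((n, k, d))
    tensor[df["instance"], df["step"], df["feature"]] = df["value"]
    return tensor


def write_design_matrix(dm: DesignMatrix, path) -> None:
    df = pd.DataFrame(dm.matrix, columns=dm.schema)
    df.insert(0, "patient_id", dm.patient_ids)
    df["label"] = dm.labels
    df.to_csv(path, index=False)


def read_design_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path)
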