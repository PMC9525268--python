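"""Class-rebalancing schemes for rare-event training data.

Two schemes are provided, matched to the two model families:

* **Bagging with random undersampling** — many balanced "bags", each
  holding *all* minority instances plus an equal number of majority
  instances drawn with replacement from the whole majority population.
  One sub-model is trained per bag and their scores averaged.
* **Minority oversampling** — each minority instance is duplicated
  ``r - 1`` times, where ``r`` is the (rounded) majority-to-minority
  ratio, producing one approximately balanced training set.

Both operate on integer indices so they compose with any dataset
container, and both are deterministic given their seed (oversampling uses
no randomness at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class BagSet:
    """Index lists into a parent dataset, one per balanced bag."""

    bags: list[np.ndarray]
    n_bags: int
    seed: int | None

    def to_json(self) -> dict:
        return {
            "n_bags": self.n_bags,
            "seed": self.seed,
            "bags": [bag.tolist() for bag in self.bags],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BagSet":
        return cls(
            bags=[np.asarray(b, dtype=int) for b in obj["bags"]],
            n_bags=obj["n_bags"],
            seed=obj["seed"],
        )


def _split_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    if idx1.size <= idx0.size:
        return idx1, idx0  # (minority, majority)
    return idx0, idx1


def make_bags(labels: np.ndarray, n_bags: int = 100, seed: int | None = None) -> BagSet:
    """Balanced bags: all minority indices + m majority draws with replacement."""
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    minority, majority = _split_classes(labels)
    m = minority.size
    rng = np.random.default_rng(seed)
    bags = [
        np.concatenate([minority, rng.choice(majority, size=m, replace=True)])
        for _ in range(n_bags)
    ]
    return BagSet(bags=bags, n_bags=n_bags, seed=seed)


def oversample_ratio(labels: np.ndarray, rounding: str = "even") -> int:
    """The duplication ratio r = round(majority / minority), at least 1."""
    minority, majority = _split_classes(labels)
    ratio = majority.size / minority.size
    if rounding == "even":
        r = round(ratio)  # round-half-to-even
    elif rounding == "floor":
        r = math.floor(ratio)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return max(1, int(r))


def oversample(labels: np.ndarray, rounding: str = "even") -> np.ndarray:
    """Deterministic index multiset with each minority index repeated r times.

    Majority indices appear once; original instance order is preserved
    (duplicates sit at the original position), so
    ``len(out) == majority + r * minority``.
    """
    labels = np.asarray(labels)
    minority, _ = _split_classes(labels)
    r = oversample_ratio(labels, rounding)
    reps = np.ones(labels.size, dtype=int)
    reps[minority] = r
    return np.repeat(np.arange(labels.size), reps)
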