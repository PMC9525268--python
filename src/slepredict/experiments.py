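"""Canned end-to-end experiments at desk scale.

These functions wire the full pipeline together — generate a synthetic
cohort, regularize it, extract windows, build features, and evaluate the
bagged Differential model — at problem sizes a single CPU handles in
minutes.  They back both the acceptance checks and the worked examples.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, generate_cohort, null_preset, signal_preset
from .ensemble import BaggedDifferentialClassifier
from .evaluation import CVPlan, auc_mann_whitney, nested_cv
from .features import build_differential
from .preprocess import preprocess_cohort
from .windowing import TaskSpec, extract_windows

#: learner settings used by the desk-scale experiments (smaller network /
#: forest than the library defaults purely to keep a laptop run short)
FAST_LEARNER_PARAMS = {
    "mlp": {"hidden_layer_sizes": (16,), "max_iter": 200},
    "forest": {"n_estimators": 50, "max_depth": 5},
}


def window_totals(seed: int = 0, n_patients: int = 925, ks=(1, 2, 3, 4, 5)) -> dict[int, int]:
    """Instance totals per window length k for the default cohort design.

    With six 6-month observation bins plus 12 months of follow-up, each of
    the ``n_patients`` patients contributes ``7 - k`` windows, so the
    totals are ``n_patients * (7 - k)`` independent of the horizon Y.
    """
    cfg = CohortConfig(n_patients=n_patients, seed=seed)
    records = generate_cohort(cfg)
    series = preprocess_cohort(records, feature_kinds=cfg.feature_kinds())
    totals = {}
    for k in ks:
        ds = extract_windows(series, TaskSpec(x_months=6 * k, y_months=12))
        totals[k] = ds.total
    return totals


def _differential_data(cfg: CohortConfig, x_months: float, y_months: float):
    records = generate_cohort(cfg)
    series = preprocess_cohort(records, feature_kinds=cfg.feature_kinds())
    ds = extract_windows(series, TaskSpec(x_months=x_months, y_months=y_months))
    dm = build_differential(ds)
    return dm


def signal_recovery_auc(
    seed: int = 0,
    n_patients: int = 925,
    x_months: float = 12.0,
    y_months: float = 12.0,
    n_bags: int = 20,
    outer_folds: int = 4,
    inner_folds: int = 5,
) -> float:
    """Mean outer-CV AUC of the bagged Differential model on the signal preset.

    The signal preset places the hazard signal predominantly in recent
    activity *change*, so between-step delta features carry it.  A small
    two-candidate grid keeps the inner search honest while desk-scale.
    """
    cfg = signal_preset(n_patients=n_patients, seed=seed)
    dm = _differential_data(cfg, x_months, y_months)
    est = BaggedDifferentialClassifier(
        n_bags=n_bags,
        learner_params=FAST_LEARNER_PARAMS,
        binary_mask=dm.binary_mask,
        random_state=seed,
    )
    candidates = [
        {"learner_params": {**FAST_LEARNER_PARAMS, "logreg": {"C": c}}} for c in (0.1, 1.0)
    ]
    plan = CVPlan(
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        seed=seed,
        inner_overrides={"n_bags": 5},
    )
    res = nested_cv(dm.matrix, dm.labels, est, candidates, plan)
    return float(res.mean.auc)


def null_auc(
    seeds=tuple(range(10)),
    n_patients: int = 600,
    x_months: float = 6.0,
    y_months: float = 12.0,
    n_bags: int = 20,
    test_fraction: float = 0.4,
) -> list[float]:
    """Held-out AUCs on the null preset (no hazard signal), one per seed.

    Each replicate generates a fresh cohort, trains the bagged Differential
    model and scores a held-out portion; values should scatter around 0.5.
    The holdout is by *patient*: overlapping windows from one patient share
    outcome intervals, so an instance-level split lets a model reach
    AUC > 0.5 on label-free data purely by recognizing training patients —
    the type-I check is only meaningful with patients held out whole.
    """
    from sklearn.model_selection import GroupShuffleSplit

    aucs = []
    for seed in seeds:
        cfg = null_preset(n_patients=n_patients, seed=seed)
        dm = _differential_data(cfg, x_months, y_months)
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        idx_train, idx_test = next(
            splitter.split(dm.matrix, dm.labels, groups=dm.patient_ids)
        )
        est = BaggedDifferentialClassifier(
            n_bags=n_bags,
            learner_params=FAST_LEARNER_PARAMS,
            binary_mask=dm.binary_mask,
            random_state=seed,
        )
        est.fit(dm.matrix[idx_train], dm.labels[idx_train])
        scores = est.decision_scores(dm.matrix[idx_test])
        aucs.append(auc_mann_whitney(dm.labels[idx_test], scores))
    return aucs
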