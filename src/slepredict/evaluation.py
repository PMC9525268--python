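"""Nested cross-validation, metrics, and the X-by-Y comparison grid.

Generalization performance is estimated with stratified outer k-fold
cross-validation; within each outer training set an inner k-fold grid
search selects hyperparameters by mean AUC, one final model is refit on
the outer training set with the chosen parameters, and the held-out fold
is scored.  A model's reported performance is the arithmetic mean of the
per-fold metric values (no pooling).  The grid runner evaluates both model
families over a factorial design of observation windows X and horizons Y
and tabulates the LSTM-minus-Differential (L-D) difference per cell.

AUC is the Mann-Whitney rank statistic (ties counted 0.5); rebalancing
(bags, oversampling) and feature scaling happen strictly inside each
training split, and every fold/bag/oversample index is logged to a run
manifest so leakage can be audited mechanically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

METRIC_NAMES = ("accuracy", "recall", "specificity", "auc", "ppv", "f1", "f_beta")


@dataclass
class MetricSet:
    """Threshold metrics at 0.5 plus rank AUC; NaN marks undefined entries."""

    accuracy: float
    recall: float
    specificity: float
    auc: float
    ppv: float
    f1: float
    f_beta: float
    beta: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Returns NaN when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    beta: float = 0.5,
) -> MetricSet:
    """Confusion-matrix metrics at ``threshold`` (predict 1 iff score >= t).

    ``f_beta`` is the general F-score (1+b^2) PPV.recall / (b^2 PPV + recall)
    with configurable beta (default 0.5, weighting precision over recall).
    Ratios with zero denominators are reported as NaN rather than 0.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = labels.size

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    recall = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    if np.isnan(recall) or np.isnan(ppv) or (ppv + recall) == 0:
        f1 = float("nan")
        f_beta = float("nan")
    else:
        f1 = 2 * ppv * recall / (ppv + recall)
        f_beta = (1 + beta**2) * ppv * recall / (beta**2 * ppv + recall)
    return MetricSet(
        accuracy=_ratio(tp + tn, n),
        recall=recall,
        specificity=_ratio(tn, tn + fp),
        auc=auc_mann_whitney(labels, scores),
        ppv=ppv,
        f1=f1,
        f_beta=f_beta,
        beta=beta,
    )


def mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Arithmetic mean over folds, ignoring NaN entries per metric."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = {
            name: float(np.nanmean([getattr(m, name) for m in metric_sets]))
            for name in METRIC_NAMES
        }
    return MetricSet(**vals, beta=metric_sets[0].beta)


@dataclass
class CVPlan:
    """Nested cross-validation plan.

    Stratification is on by default because unstratified 20-fold splits at
    ~1-2% prevalence frequently yield positive-free folds.  When the rarer
    class has fewer instances than the requested folds, the fold count is
    reduced automatically (with a warning).  ``group_by_patient`` switches
    to grouped folds so a patient's overlapping windows never straddle a
    train/test boundary.
    """

    outer_folds: int = 20
    inner_folds: int = 20
    stratified: bool = True
    group_by_patient: bool = False
    seed: int = 0
    #: estimator parameter overrides applied only during inner-CV candidate
    #: scoring (e.g. {"n_bags": 5} to keep the grid search desk-scale)
    inner_overrides: dict = field(default_factory=dict)


def make_folds(
    y: np.ndarray,
    n_folds: int,
    stratified: bool = True,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs; auto-reduces folds for very rare classes."""
    y = np.asarray(y)
    if groups is not None:
        splitter = GroupKFold(n_splits=n_folds)
        return list(splitter.split(np.zeros_like(y), y, groups))
    if stratified:
        min_class = int(np.bincount(y.astype(int)).min())
        if min_class < n_folds:
            warnings.warn(
                f"reducing folds from {n_folds} to {min_class}: "
                "rarer class has too few instances for stratification"
            )
            n_folds = max(2, min_class)
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros_like(y), y))
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y)))


@dataclass
class NestedCVResult:
    per_fold: list[MetricSet]
    chosen_params: list[dict]
    mean: MetricSet
    manifest: dict


def _global_rebalance_indices(model, train_idx: np.ndarray) -> dict:
    """Map a fitted model's internal rebalancing indices to global indices."""
    out = {}
    if hasattr(model, "bags_"):
        out["bags"] = [train_idx[bag].tolist() for bag in model.bags_.bags]
    if hasattr(model, "oversample_indices_"):
        out["oversample"] = train_idx[model.oversample_indices_].tolist()
    return out


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    estimator,
    candidates: list[dict] | None,
    plan: CVPlan,
    groups: np.ndarray | None = None,
    beta: float = 0.5,
) -> NestedCVResult:
    """Outer-CV performance with inner-CV hyperparameter selection by AUC.

    ``candidates`` is a list of estimator parameter dicts; for each outer
    fold the candidate with the highest mean inner-fold AUC (first maximum
    on ties) is chosen, one model is refit on the full outer training set
    with those parameters, and the held-out fold is scored.  With a single
    candidate (or ``None``) the inner loop is skipped.
    """
    y = np.asarray(y).astype(int)
    candidates = candidates or [{}]
    outer = make_folds(
        y,
        plan.outer_folds,
        plan.stratified,
        groups if plan.group_by_patient else None,
        seed=plan.seed,
    )
    per_fold: list[MetricSet] = []
    chosen: list[dict] = []
    manifest: dict = {"outer_folds": [], "plan": asdict(plan)}

    for fold_i, (train_idx, test_idx) in enumerate(outer):
        if len(candidates) > 1:
            inner = make_folds(
                y[train_idx],
                plan.inner_folds,
                plan.stratified,
                (groups[train_idx] if (groups is not None and plan.group_by_patient) else None),
                seed=plan.seed + 1000 + fold_i,
            )
            mean_aucs = []
            for cand in candidates:
                aucs = []
                for in_train, in_val in inner:
                    est = clone(estimator).set_params(**{**cand, **plan.inner_overrides})
                    est.fit(X[train_idx][in_train], y[train_idx][in_train])
                    s = est.predict_proba(X[train_idx][in_val])[:, 1]
                    aucs.append(auc_mann_whitney(y[train_idx][in_val], s))
                mean_aucs.append(float(np.nanmean(aucs)))
            best = int(np.argmax(mean_aucs))
        else:
            best = 0
        params = candidates[best]
        chosen.append(params)

        model = clone(estimator).set_params(**params)
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_proba(X[test_idx])[:, 1]
        per_fold.append(compute_metrics(y[test_idx], scores, beta=beta))

        manifest["outer_folds"].append(
            {
                "fold": fold_i,
                "train_indices": train_idx.tolist(),
                "test_indices": test_idx.tolist(),
                "chosen_params": {k: repr(v) for k, v in params.items()},
                "scaler_fit_indices": train_idx.tolist(),
                **_global_rebalance_indices(model, train_idx),
            }
        )

    return NestedCVResult(
        per_fold=per_fold,
        chosen_params=chosen,
        mean=mean_metrics(per_fold),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# factorial X-by-Y grid

@dataclass
class MetricsGrid:
    """Per-(X, Y, model) results; supports the L-D comparison table."""

    entries: dict = field(default_factory=dict)  # (x, y, model) -> dict
    errors: dict = field(default_factory=dict)

    def mean_table(self, metric: str) -> pd.DataFrame:
        rows = []
        for (x, yh, model), entry in self.entries.items():
            rows.append((x, yh, model, getattr(entry["mean"], metric)))
        df = pd.DataFrame(rows, columns=["x_months", "y_months", "model", metric])
        return df.pivot_table(index="x_months", columns=["model", "y_months"], values=metric)

    def ld_table(self, metric: str) -> pd.DataFrame:
        """LSTM minus Differential, cell by cell."""
        rows = {}
        for (x, yh, model), entry in self.entries.items():
            rows.setdefault((x, yh), {})[model] = getattr(entry["mean"], metric)
        recs = []
        for (x, yh), by_model in sorted(rows.items()):
            if "LSTM" in by_model and "Differential" in by_model:
                recs.append((x, yh, by_model["LSTM"] - by_model["Differential"]))
        return pd.DataFrame(recs, columns=["x_months", "y_months", "L-D"]).pivot(
            index="x_months", columns="y_months", values="L-D"
        )


def run_grid(
    series_list,
    x_list,
    y_list,
    models: dict,
    plan: CVPlan,
    label_followup: float = 12.0,
) -> MetricsGrid:
    """Run every (X, Y, model) cell; failures are recorded, not fatal.

    ``models`` maps a model name (conventionally 'Differential' / 'LSTM')
    to a ``(estimator, candidates, builder)`` triple, where ``builder``
    turns a :class:`WindowedDataset` into (X_array, labels, patient_ids) —
    see :func:`differential_builder` and :func:`lstm_builder`.
    """
    from .windowing import TaskSpec, extract_windows

    grid = MetricsGrid()
    for x_months in x_list:
        for y_months in y_list:
            task = TaskSpec(x_months=x_months, y_months=y_months)
            ds = extract_windows(series_list, task, label_followup=label_followup)
            for name, (estimator, candidates, builder) in models.items():
                try:
                    X_arr, labels, pids = builder(ds)
                    res = nested_cv(X_arr, labels, estimator, candidates, plan, groups=pids)
                    grid.entries[(x_months, y_months, name)] = {
                        "mean": res.mean,
                        "per_fold": res.per_fold,
                        "chosen_params": res.chosen_params,
                        "total": ds.total,
                        "class1": ds.class1_count,
                    }
                except Exception as exc:  # record and continue with other cells
                    grid.errors[(x_months, y_months, name)] = repr(exc)
    return grid


def differential_builder(ds):
    from .features import build_differential

    dm = build_differential(ds)
    return dm.matrix, dm.labels, dm.patient_ids


def lstm_builder(ds):
    from .features import build_lstm_tensor

    st = build_lstm_tensor(ds)
    return st.tensor, st.labels, st.patient_ids


def report(grid: MetricsGrid, outdir) -> dict[str, pd.DataFrame]:
    """Write per-metric CSV + markdown tables with D, L and L-D columns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for metric in METRIC_NAMES:
        rows = {}
        for (x, yh, model), entry in grid.entries.items():
            rows.setdefault((x, yh), {})[model] = getattr(entry["mean"], metric)
        recs = []
        for (x, yh), by_model in sorted(rows.items()):
            d = by_model.get("Differential", float("nan"))
            l = by_model.get("LSTM", float("nan"))
            recs.append((x, yh, d, l, l - d))
        df = pd.DataFrame(recs, columns=["x_months", "y_months", "D", "L", "L-D"])
        df.to_csv(outdir / f"{metric}.csv", index=False)
        (outdir / f"{metric}.md").write_text(df.to_markdown(index=False))
        tables[metric] = df
    if grid.errors:
        (outdir / "errors.json").write_text(
            json.dumps({repr(k): v for k, v in grid.errors.items()}, indent=2)
        )
    return tables
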