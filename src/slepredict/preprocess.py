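"""Regularize irregular visit records into 6-month-binned, imputed series.

Binning aggregates the visits falling in each half-year interval with a
category-appropriate rule: laboratory values are averaged (multiple lab
visits in one interval act as one averaged visit), binary
manifestation/medication flags take the maximum (present if recorded at any
visit in the interval), and utilization counts are summed.  Cells with no
observation stay missing and are then filled per feature per patient:
interior gaps by piecewise-linear interpolation between the nearest
observed bins, leading/trailing gaps by extrapolating the least-squares
line through that feature's observed points (constant when only one point
was observed).  A feature never observed for a patient falls back to the
cohort-level feature mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord


@dataclass
class RegularSeries:
    """Per-patient matrix of binned clinical features plus outcome support.

    ``values`` is ``n_bins x n_features``; after imputation it has no
    missing entries.  ``observed_mask`` marks cells that came from real
    visit data; imputation never changes those cells.
    """

    patient_id: str
    bin_months: float
    values: np.ndarray
    observed_mask: np.ndarray
    demographics: np.ndarray
    events: list[float]
    feature_kinds: list[str] = field(default_factory=list)
    followup_months: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def bin_visits(
    record: PatientRecord,
    bin_months: float = 6.0,
    feature_kinds: list[str] | None = None,
) -> RegularSeries:
    """Aggregate a patient's visits into fixed-width bins.

    Bin ``b`` covers ``[b*bin_months, (b+1)*bin_months)`` (left-closed).
    Aggregation per feature kind: ``continuous`` -> mean, ``binary`` -> max,
    ``count`` -> sum.  A cell with no observation in its bin is NaN.
    """
    if bin_months <= 0:
        raise ValueError("bin_months must be positive")
    n_features = len(record.visits[0][1]) if record.visits else (
        len(feature_kinds) if feature_kinds else 0
    )
    if feature_kinds is None:
        feature_kinds = ["continuous"] * n_features
    n_bins = int(round(record.obs_months / bin_months))

    values = np.full((n_bins, n_features), np.nan)
    observed = np.zeros((n_bins, n_features), dtype=bool)

    by_bin: dict[int, list[np.ndarray]] = {}
    for tv, vals in record.visits:
        if not 0.0 <= tv < record.obs_months:
            raise ValueError(
                f"visit time {tv} outside patient timeline [0, {record.obs_months})"
            )
        by_bin.setdefault(int(tv // bin_months), []).append(vals)

    kinds_arr = np.asarray(feature_kinds)
    for b, stack in by_bin.items():
        mat = np.vstack(stack)  # visits x features, NaN = unmeasured
        has_obs = ~np.all(np.isnan(mat), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            agg = np.where(
                kinds_arr == "binary",
                np.nanmax(mat, axis=0, initial=-np.inf),
                np.where(
                    kinds_arr == "count",
                    np.nansum(mat, axis=0),
                    np.nanmean(mat, axis=0),
                ),
            )
        values[b, has_obs] = agg[has_obs]
        observed[b, has_obs] = True

    return RegularSeries(
        patient_id=record.patient_id,
        bin_months=bin_months,
        values=values,
        observed_mask=observed,
        demographics=record.demographics.copy(),
        events=list(record.events),
        feature_kinds=list(feature_kinds),
        followup_months=record.followup_months,
    )


def _fill_feature(col: np.ndarray, obs: np.ndarray, method: str) -> np.ndarray:
    """Fill the missing entries of one feature column from its observed cells."""
    idx = np.flatnonzero(obs)
    out = col.copy()
    missing = np.flatnonzero(~obs)
    if missing.size == 0:
        return out
    x_obs = idx.astype(float)
    y_obs = col[idx]
    if idx.size == 1:
        out[missing] = y_obs[0]
        return out
    if method == "least_squares":
        slope, intercept = np.polyfit(x_obs, y_obs, 1)
        out[missing] = slope * missing + intercept
        return out
    # hybrid: interior pass-through interpolation, least-squares edges
    slope, intercept = np.polyfit(x_obs, y_obs, 1)
    lo, hi = idx[0], idx[-1]
    for m in missing:
        if lo <= m <= hi:
            out[m] = np.interp(m, x_obs, y_obs)
        else:
            out[m] = slope * m + intercept
    return out


def impute_series(
    series: RegularSeries,
    fallback: np.ndarray | None = None,
    method: str = "hybrid",
) -> RegularSeries:
    """Return a copy of ``series`` with every missing cell filled.

    ``method='hybrid'`` (default): interior gaps by piecewise-linear
    interpolation through the observed points, edge gaps by extrapolating
    the least-squares line.  ``method='least_squares'`` fits one line to
    all observed points and fills every gap from it.  Binary features are
    clipped to [0, 1] after imputation; observed cells are never altered.

    ``fallback`` supplies per-feature values (typically cohort means) for
    features with no observation at all for this patient; without it such
    features are filled with 0 and a warning is emitted.
    """
    if method not in ("hybrid", "least_squares"):
        raise ValueError(f"unknown imputation method {method!r}")
    values = series.values.copy()
    mask = series.observed_mask
    kinds = series.feature_kinds or ["continuous"] * series.n_features
    for j in range(series.n_features):
        obs = mask[:, j]
        if not obs.any():
            if fallback is not None:
                fill = float(fallback[j])
            else:
                fill = 0.0
                warnings.warn(
                    f"feature {j} never observed for patient "
                    f"{series.patient_id}; filled with 0 (no fallback given)"
                )
            values[:, j] = fill
            continue
        col = _fill_feature(values[:, j], obs, method)
        if kinds[j] == "binary":
            imput = ~obs
            col[imput] = np.clip(col[imput], 0.0, 1.0)
        values[:, j] = np.where(obs, series.values[:, j], col)

    return RegularSeries(
        patient_id=series.patient_id,
        bin_months=series.bin_months,
        values=values,
        observed_mask=mask.copy(),
        demographics=series.demographics.copy(),
        events=list(series.events),
        feature_kinds=list(kinds),
        followup_months=series.followup_months,
    )


def cohort_feature_means(series_list: list[RegularSeries]) -> np.ndarray:
    """Per-feature mean over all observed cells of all patients (NaN-safe)."""
    n_features = series_list[0].n_features
    totals = np.zeros(n_features)
    counts = np.zeros(n_features)
    for s in series_list:
        obs = s.observed_mask
        vals = np.where(obs, s.values, 0.0)
        totals += vals.sum(axis=0)
        counts += obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = totals / counts
    return np.where(counts > 0, means, 0.0)


def preprocess_cohort(
    records: list[PatientRecord],
    bin_months: float = 6.0,
    feature_kinds: list[str] | None = None,
    method: str = "hybrid",
) -> list[RegularSeries]:
    """Bin then impute every patient; never-observed features get cohort means."""
    binned = [bin_visits(r, bin_months, feature_kinds) for r in records]
    fallback = cohort_feature_means(binned)
    return [impute_series(s, fallback=fallback, method=method) for s in binned]


# ---------------------------------------------------------------------------
# wide CSV round trip (one row per patient-bin + observed-mask companion)

def write_series(series_list: list[RegularSeries], outdir, feature_names: list[str]) -> None:
    from pathlib import Path
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vrows, mrows = [], []
    for s in series_list:
        for b in range(s.n_bins):
            vrows.append((s.patient_id, b, *s.values[b]))
            mrows.append((s.patient_id, b, *s.observed_mask[b].astype(int)))
    cols = ["patient_id", "bin", *feature_names]
    pd.DataFrame(vrows, columns=cols).to_csv(outdir / "series_values.csv", index=False)
    pd.DataFrame(mrows, columns=cols).to_csv(outdir / "series_mask.csv", index=False)
    meta = {
        s.patient_id: {
            "bin_months": s.bin_months,
            "demographics": list(map(float, s.demographics)),
            "events": list(map(float, s.events)),
            "feature_kinds": s.feature_kinds,
            "followup_months": s.followup_months,
        }
        for s in series_list
    }
    (outdir / "series_meta.json").write_text(json.dumps(meta))


def read_series(indir) -> tuple[list[RegularSeries], list[str]]:
    from pathlib import Path
    import json

    indir = Path(indir)
    meta = json.loads((indir / "series_meta.json").read_text())
    vals_df = pd.read_csv(indir / "series_values.csv")
    mask_df = pd.read_csv(indir / "series_mask.csv")
    feature_names = [c for c in vals_df.columns if c not in ("patient_id", "bin")]
    out = []
    for pid, m in meta.items():
        v = vals_df[vals_df["patient_id"] == pid].sort_values("bin")
        k = mask_df[mask_df["patient_id"] == pid].sort_values("bin")
        out.append(
            RegularSeries(
                patient_id=pid,
                bin_months=m["bin_months"],
                values=v[feature_names].to_numpy(dtype=float),
                observed_mask=k[feature_names].to_numpy(dtype=bool),
                demographics=np.asarray(m["demographics"], dtype=float),
                events=list(m["events"]),
                feature_kinds=m["feature_kinds"],
                followup_months=m["followup_months"],
            )
        )
    return out, feature_names
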