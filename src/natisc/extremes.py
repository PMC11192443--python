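"""Peak/trough time-point removal and the random-removal resampling null.

High ISC for a condition could in principle be carried by a handful of
strong-response scenes rather than by continuous stimulus tracking.  To
test this, time points where the group-average BOLD series (averaged
over participants and fROIs, then z-normalized) exceeds +1 (peaks) or
falls below -1 (troughs) are deleted from every participant's series
and ISC is recomputed; the result is benchmarked against a null
distribution built by deleting the same number of randomly chosen time
points many times (default 10,000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import stream_rng
from .isc import TimeCourseSet, _loo_r, compute_isc_table, fisher_z
from .stats import fdr_bh

__all__ = [
    "ExtremePointSet",
    "NullDistribution",
    "group_average_series",
    "threshold_indices",
    "detect_extremes",
    "matched_trough_indices",
    "removed_isc",
    "removed_mean_isc",
    "random_removal_null",
    "peak_vs_trough_test",
    "peak_vs_trough_suite",
]


@dataclass
class ExtremePointSet:
    """Peak or trough time points for one condition."""

    condition: str
    polarity: str  # "peak" | "trough"
    indices: np.ndarray  # sorted, post-trim coordinates
    threshold: float
    group_series: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.group_series = np.asarray(self.group_series, dtype=float)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition": self.condition,
                    "polarity": self.polarity,
                    "indices": self.indices.tolist(),
                    "threshold": self.threshold,
                    "group_series": self.group_series.tolist(),
                },
                fh,
            )


@dataclass
class NullDistribution:
    """Mean ISC under repeated random removal of m time points."""

    condition: str
    m_removed: int
    n_iter: int
    values: np.ndarray
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_iter:
            raise ValueError("values length must equal n_iter")

    def p_value(self, observed: float) -> float:
        """One-tailed lower empirical p with add-one smoothing.

        Removal of genuinely informative time points can only be
        expected to lower the mean ISC, hence the lower tail; add-one
        smoothing avoids p = 0 at finite n_iter.
        """
        return (1 + int(np.sum(self.values <= observed))) / (1 + self.n_iter)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> dict:
        return {q: float(np.quantile(self.values, q)) for q in qs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition": self.condition,
                    "m_removed": self.m_removed,
                    "n_iter": self.n_iter,
                    "seed": self.seed,
                    "values": self.values.tolist(),
                },
                fh,
            )


def group_average_series(tcs: TimeCourseSet, condition: str) -> np.ndarray:
    """Average series over all participating participants and all fROIs."""
    series = [x for (p, c, f), x in tcs.data.items() if c == condition]
    if not series:
        raise KeyError(f"condition {condition!r} not present")
    return np.mean(np.vstack(series), axis=0)


def threshold_indices(z_series: np.ndarray, polarity: str, threshold: float = 1.0) -> np.ndarray:
    """Indices where a z-normalized series exceeds the threshold (strict)."""
    z_series = np.asarray(z_series, dtype=float)
    if polarity == "peak":
        return np.nonzero(z_series > threshold)[0]
    if polarity == "trough":
        return np.nonzero(z_series < -threshold)[0]
    raise ValueError(f"polarity must be 'peak' or 'trough', got {polarity!r}")


def detect_extremes(
    tcs: TimeCourseSet, condition: str, polarity: str, threshold: float = 1.0
) -> ExtremePointSet:
    """Find peak (z > +thr) or trough (z < -thr) time points of a condition.

    The detection series is the grand average across participants and
    fROIs, z-normalized (n-1 convention).  Expects preprocessed series;
    indices are therefore in post-trim coordinates.
    """
    g = group_average_series(tcs, condition)
    sd = g.std(ddof=1)
    if sd == 0:
        raise ValueError("constant group-average series cannot be z-normalized")
    z = (g - g.mean()) / sd
    idx = threshold_indices(z, polarity, threshold)
    return ExtremePointSet(
        condition=condition, polarity=polarity, indices=idx, threshold=threshold, group_series=z
    )


def matched_trough_indices(tcs: TimeCourseSet, condition: str, m: int) -> np.ndarray:
    """The m lowest-valued time points of the condition's group series.

    Used to equate the number of removed trough points with the number
    of peak points in the head-to-head peak-vs-trough comparison.
    """
    g = group_average_series(tcs, condition)
    if m < 0 or m > len(g):
        raise ValueError("m out of range")
    order = np.lexsort((np.arange(len(g)), g))  # ascending value, index tie-break
    return np.sort(order[:m])


def _delete_columns(X: np.ndarray, indices: np.ndarray) -> np.ndarray:
    if len(indices) == 0:
        return X
    keep = np.ones(X.shape[1], dtype=bool)
    keep[indices] = False
    return X[:, keep]


def removed_isc(tcs: TimeCourseSet, condition: str, indices) -> pd.DataFrame:
    """ISC table for one condition after deleting the listed time points.

    The same deletion is applied to every participant's series and every
    fROI; removed samples are deleted outright (never interpolated) and
    the correlation is computed on the concatenated remainder.
    """
    indices = np.asarray(indices, dtype=int)
    T = tcs.n_timepoints(condition)
    if len(indices) and (indices.min() < 0 or indices.max() >= T):
        raise ValueError("removal indices out of range")
    if len(np.unique(indices)) != len(indices):
        raise ValueError("removal indices must be distinct")
    if T - len(indices) < 3:
        raise ValueError("removal would leave fewer than 3 samples")
    sub = TimeCourseSet(
        data={
            k: _delete_columns(np.asarray(x)[None, :], indices)[0]
            for k, x in tcs.data.items()
            if k[1] == condition
        },
        tr_s=tcs.tr_s,
        onset_exclusion_s=0.0,
        condition_types=dict(tcs.condition_types),
    )
    return compute_isc_table(sub)


def removed_mean_isc(tcs: TimeCourseSet, condition: str, indices) -> float:
    """Mean Fisher z across participants and fROIs after removal."""
    return float(removed_isc(tcs, condition, indices)["z"].mean())


def random_removal_null(
    tcs: TimeCourseSet,
    condition: str,
    m: int,
    n_iter: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of mean ISC under random removal of m time points.

    Each draw deletes m distinct, uniformly chosen time points from
    every participant's series, recomputes per-fROI leave-one-out ISCs,
    and stores the mean Fisher z across participants and fROIs.  Draws
    use a per-condition substream of ``seed``, so the null is
    reproducible independent of evaluation order.
    """
    T = tcs.n_timepoints(condition)
    if not (0 <= m < T - 3):
        raise ValueError(f"m must satisfy 0 <= m < T - 3 (T = {T})")
    frois = tcs.frois(condition)
    mats = [tcs.matrix(condition, f)[1] for f in frois]
    rng = stream_rng(seed, "null", condition)
    values = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(T, size=m, replace=False) if m else np.empty(0, dtype=int)
        zs = []
        for X in mats:
            r = _loo_r(_delete_columns(X, idx))
            zs.append(fisher_z(r))
        values[it] = float(np.mean(np.concatenate(zs)))
    return NullDistribution(
        condition=condition, m_removed=m, n_iter=n_iter, values=values, seed=seed
    )


def peak_vs_trough_test(
    peak_isc: pd.DataFrame, trough_isc: pd.DataFrame
) -> tuple[float, int, float]:
    """Two-sample t test of peak-removed vs trough-removed Fisher z.

    Observations are the per-(participant x fROI) z values of one
    condition; two-tailed, pooled variance, df = n1 + n2 - 2.  The
    caller is responsible for matching the removal counts (use
    :func:`matched_trough_indices`).
    """
    a = peak_isc["z"].to_numpy(dtype=float)
    b = trough_isc["z"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.array_equal(a, b):
        return 0.0, len(a) + len(b) - 2, 1.0
    t, p = sps.ttest_ind(a, b)
    return float(t), len(a) + len(b) - 2, float(p)


def peak_vs_trough_suite(
    tcs: TimeCourseSet, conditions, threshold: float = 1.0
) -> pd.DataFrame:
    """Peak- vs trough-removed comparison for several conditions, with FDR.

    For each condition: peaks are all points with group z > threshold
    (count m); troughs are the m lowest-valued points (count-matched);
    the two removed-ISC tables are compared with a two-sample t test and
    p values are FDR-corrected across the conditions tested.
    """
    rows = []
    for c in conditions:
        peaks = detect_extremes(tcs, c, "peak", threshold)
        m = len(peaks.indices)
        troughs = matched_trough_indices(tcs, c, m)
        pk_tab = removed_isc(tcs, c, peaks.indices)
        tr_tab = removed_isc(tcs, c, troughs)
        t, df, p = peak_vs_trough_test(pk_tab, tr_tab)
        rows.append(
            {
                "condition": c,
                "m_removed": m,
                "peak_mean_z": float(pk_tab["z"].mean()),
                "trough_mean_z": float(tr_tab["z"].mean()),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].tolist())
    return out
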