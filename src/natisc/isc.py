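"""Leave-one-out intersubject correlation (ISC) over region-level BOLD series.

The central object is :class:`TimeCourseSet`, a collection of BOLD time
courses keyed by (participant, condition, fROI).  ISC for a participant
is the Pearson correlation between their time course and the average
time course of the remaining participants for the same condition and
fROI; correlations are Fisher-transformed (z = atanh r) before any
parametric statistics.

Preprocessing follows the naturalistic-fMRI convention: the first 6 s
after stimulus onset are discarded (to exclude the initial hemodynamic
rise relative to fixation) and each series is temporally z-scored.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TimeCourseSet",
    "preprocess",
    "loo_isc",
    "fisher_z",
    "compute_isc_table",
    "rest_baseline_test",
    "mean_isc_by_type",
]

ISC_COLUMNS = ["participant", "condition", "condition_type", "froi", "r", "z", "n_timepoints"]


@dataclass
class TimeCourseSet:
    """BOLD time courses keyed by (participant, condition, froi).

    Parameters
    ----------
    data
        Mapping from ``(participant, condition, froi)`` to a 1-D float
        array.  Within a condition all series must have equal length.
    tr_s
        Repetition time (sampling interval) in seconds.
    onset_exclusion_s
        Seconds to drop at stimulus onset during :func:`preprocess`.
    condition_types
        Mapping from condition name to its condition-type label
        (``"+M/-L"``, ``"+M/+L"``, ``"-M/-L"``, or ``"rest"``).
    """

    data: dict = field(default_factory=dict)
    tr_s: float = 2.0
    onset_exclusion_s: float = 6.0
    condition_types: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.validate()

    # -- introspection -------------------------------------------------
    def conditions(self) -> list:
        return sorted({c for (_, c, _) in self.data})

    def frois(self, condition: str | None = None) -> list:
        return sorted({f for (_, c, f) in self.data if condition is None or c == condition})

    def participants(self, condition: str | None = None, froi: str | None = None) -> list:
        return sorted(
            {
                p
                for (p, c, f) in self.data
                if (condition is None or c == condition) and (froi is None or f == froi)
            }
        )

    def n_timepoints(self, condition: str) -> int:
        for (p, c, f), x in self.data.items():
            if c == condition:
                return len(x)
        raise KeyError(f"condition {condition!r} not present")

    def validate(self) -> None:
        lengths: dict = {}
        for (p, c, f), x in self.data.items():
            x = np.asarray(x, dtype=float)
            if x.ndim != 1:
                raise ValueError(f"series for {(p, c, f)} is not 1-D")
            if c in lengths and lengths[c] != len(x):
                raise ValueError(
                    f"unequal series lengths within condition {c!r}: "
                    f"{lengths[c]} vs {len(x)} for participant {p!r}"
                )
            lengths[c] = len(x)

    def matrix(self, condition: str, froi: str) -> tuple[list, np.ndarray]:
        """Return (participants, X) with X of shape (n_participants, T)."""
        ps = [p for (p, c, f) in self.data if c == condition and f == froi]
        ps.sort()
        if not ps:
            raise KeyError(f"no series for condition {condition!r}, froi {froi!r}")
        X = np.vstack([np.asarray(self.data[(p, condition, froi)], dtype=float) for p in ps])
        return ps, X

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (p, c, f), x in sorted(self.data.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": c,
                        "froi": f,
                        "t_index": np.arange(len(x)),
                        "bold": np.asarray(x, dtype=float),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        tr_s: float = 2.0,
        onset_exclusion_s: float = 6.0,
        condition_types: Mapping | None = None,
    ) -> "TimeCourseSet":
        data = {}
        for (p, c, f), g in df.groupby(["participant", "condition", "froi"], sort=True):
            g = g.sort_values("t_index")
            data[(p, c, f)] = g["bold"].to_numpy(dtype=float)
        return cls(
            data=data,
            tr_s=tr_s,
            onset_exclusion_s=onset_exclusion_s,
            condition_types=dict(condition_types or {}),
        )

    @classmethod
    def from_tsv(cls, path, **kw) -> "TimeCourseSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **kw)

    def copy(self) -> "TimeCourseSet":
        return dataclasses.replace(
            self,
            data={k: np.array(v, dtype=float) for k, v in self.data.items()},
            condition_types=dict(self.condition_types),
        )


def _zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant series cannot be z-scored")
    return (x - x.mean()) / sd


def preprocess(tcs: TimeCourseSet) -> TimeCourseSet:
    """Drop the onset-exclusion window and temporally z-score each series.

    The first ``round(onset_exclusion_s / tr_s)`` samples are removed
    (3 samples for the default 6 s at TR = 2 s) and every remaining
    series is z-scored over time with the n-1 variance convention.
    A constant series raises, naming the offending record.
    """
    n_drop = int(round(tcs.onset_exclusion_s / tcs.tr_s))
    out = {}
    for key, x in tcs.data.items():
        x = np.asarray(x, dtype=float)
        if len(x) <= n_drop + 2:
            raise ValueError(
                f"series for {key} has {len(x)} samples; too short for a "
                f"{n_drop}-sample onset exclusion"
            )
        trimmed = x[n_drop:]
        try:
            out[key] = _zscore(trimmed)
        except ValueError as e:
            raise ValueError(f"record {key}: {e}") from None
    new = tcs.copy()
    new.data = out
    new.onset_exclusion_s = 0.0
    return new


def _loo_r(X: np.ndarray) -> np.ndarray:
    """Leave-one-out Pearson r for every row of X (shape n x T), vectorized."""
    n, T = X.shape
    if n < 2:
        raise ValueError("leave-one-out ISC requires at least 2 participants")
    total = X.sum(axis=0)
    M = (total[None, :] - X) / (n - 1)  # row i: average of the others
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    num = (Xc * Mc).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Mc**2).sum(axis=1))
    if np.any(den == 0):
        bad = int(np.nonzero(den == 0)[0][0])
        raise ValueError(
            f"zero-variance series or leave-one-out average (row {bad}); r undefined"
        )
    return num / den


def loo_isc(tcs: TimeCourseSet, condition: str, froi: str) -> list[tuple]:
    """Leave-one-out ISC for one (condition, fROI) cell.

    For each participating participant i, returns ``(participant, r_i)``
    where ``r_i`` is the Pearson correlation between participant i's
    series and the plain average of the remaining participants' series
    (the average is not re-z-scored).  Only participants who saw the
    condition enter the average.
    """
    ps, X = tcs.matrix(condition, froi)
    r = _loo_r(X)
    return list(zip(ps, r.tolist()))


def fisher_z(r, clip: bool = False):
    """Fisher transform z = atanh(r).

    ``|r| = 1`` raises by default because downstream mixed models cannot
    absorb infinities; pass ``clip=True`` to clamp at 1 - 1e-7 instead.
    Accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlation outside [-1, 1]")
    if np.any(np.abs(arr) == 1):
        if not clip:
            raise ValueError("|r| = 1 has infinite Fisher z; pass clip=True to clamp")
        arr = np.clip(arr, -(1 - 1e-7), 1 - 1e-7)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def compute_isc_table(tcs: TimeCourseSet, clip: bool = False) -> pd.DataFrame:
    """Leave-one-out ISC + Fisher z for every (condition, fROI) cell.

    Expects a preprocessed :class:`TimeCourseSet`.  Returns a long-format
    DataFrame with one row per participating (participant, condition,
    froi): columns participant, condition, condition_type, froi, r, z,
    n_timepoints.
    """
    rows = []
    for c in tcs.conditions():
        ctype = tcs.condition_types.get(c, "")
        T = tcs.n_timepoints(c)
        for f in tcs.frois(c):
            for p, r in loo_isc(tcs, c, f):
                rows.append((p, c, ctype, f, r, fisher_z(r, clip=clip), T))
    return pd.DataFrame(rows, columns=ISC_COLUMNS)


def mean_isc_by_type(isc: pd.DataFrame, value: str = "r") -> pd.Series:
    """Mean ISC per condition type (participants and fROIs pooled)."""
    return isc.groupby("condition_type")[value].mean()


def rest_baseline_test(isc: pd.DataFrame) -> tuple[float, int, float]:
    """One-tailed t test of resting-state ISCs against zero.

    Each participant contributes their mean Fisher z across fROIs; the
    test is one-sample, one-tailed (H1: mean > 0), df = n - 1.  A
    significant result would indicate spurious intersubject coupling in
    the acquisition/analysis chain.
    """
    rest = isc[isc["condition"] == "rest"] if "rest" in set(isc["condition"]) else isc
    per_p = rest.groupby("participant")["z"].mean()
    n = len(per_p)
    if n < 2:
        raise ValueError("rest baseline test needs at least 2 participants")
    vals = per_p.to_numpy()
    if np.allclose(vals, vals[0]) and math.isclose(vals[0], 0.0, abs_tol=1e-300):
        return 0.0, n - 1, 0.5
    t, p = sps.ttest_1samp(vals, 0.0, alternative="greater")
    return float(t), n - 1, float(p)
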