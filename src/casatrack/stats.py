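"""Method-comparison statistics for validating one tracker against another.

The reproducibility of a motility parameter measured by two trackers on the
same fields of view is summarised by a coefficient of variation defined as
the sample SD of the paired differences divided by the overall (pooled)
mean of both methods, in percent; values below 10% are conventionally taken
as acceptable inter-method agreement.  Group comparisons use the standard
independent-samples t-test and one-way ANOVA.  Normality (Shapiro–Wilk) and
homoscedasticity (Levene) checks are run as advisory diagnostics and
logged, not used as gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedStatisticError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedComparison:
    """Agreement summary for one motility parameter measured by two methods."""

    parameter_name: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    cv_percent: float | None
    t_statistic: float | None
    p_value: float | None


def coefficient_of_variation(values_a, values_b) -> float:
    """CV%% = 100 * SD(a - b) / mean(a ∪ b), with SD using ddof=1.

    The "overall mean" is the pooled mean of both methods' values, which
    makes the statistic symmetric in the two methods.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise InvalidInputError("values_a and values_b must be paired 1-D sequences")
    if len(a) < 2:
        raise InvalidInputError("CV needs at least 2 paired values")
    overall_mean = float(np.concatenate([a, b]).mean())
    if overall_mean == 0:
        raise UndefinedStatisticError("CV undefined: overall mean is zero")
    return float(100.0 * np.std(a - b, ddof=1) / overall_mean)


def compare_two_methods(
    values_a,
    values_b,
    parameter_name: str = "",
    *,
    welch: bool = False,
) -> PairedComparison:
    """Two-sample t-test (pooled-variance by default; Welch via flag) plus CV.

    The CV is computed when the samples are paired (equal length); otherwise
    it is reported as None.  Degenerate (zero-variance, equal-mean) samples
    yield an undefined t statistic, reported as None.  Shapiro–Wilk and
    Levene diagnostics are logged at INFO level.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs at least 2 values")

    for name, grp in (("a", a), ("b", b)):
        if len(grp) >= 3 and np.ptp(grp) > 0:
            w, p = sps.shapiro(grp)
            log.info("Shapiro-Wilk group %s: W=%.4f p=%.4f", name, w, p)
    if np.ptp(a) > 0 or np.ptp(b) > 0:
        lev, p_lev = sps.levene(a, b)
        log.info("Levene: W=%.4f p=%.4f", lev, p_lev)

    cv = None
    if len(a) == len(b):
        try:
            cv = coefficient_of_variation(a, b)
        except UndefinedStatisticError:
            cv = None

    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p_val = None, None
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat = float(res.statistic)
        p_val = float(res.pvalue)
        if np.isnan(t_stat):
            t_stat, p_val = None, None

    return PairedComparison(
        parameter_name=parameter_name,
        values_a=tuple(float(v) for v in a),
        values_b=tuple(float(v) for v in b),
        cv_percent=cv,
        t_statistic=t_stat,
        p_value=p_val,
    )


def compare_multi_group(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA across >= 2 groups; returns (F, p)."""
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise InvalidInputError("every group needs at least 2 values")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# TrackMate interoperability
# ---------------------------------------------------------------------------

#: Required columns of a TrackMate spots export.
TRACKMATE_COLUMNS = {"TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"}


def read_trackmate(path, fps: float | None = None) -> pd.DataFrame:
    """Convert a TrackMate spots CSV export to the internal track schema.

    Expects columns TRACK_ID, FRAME, POSITION_X, POSITION_Y with positions
    in calibrated units (μm).  TrackMate writes up to three extra header
    rows (full names, units, ...) under the column line; rows whose FRAME
    is non-numeric are dropped.  ``time_s`` is FRAME / fps when ``fps`` is
    given, else the POSITION_T column if present.
    """
    df = pd.read_csv(path)
    missing = TRACKMATE_COLUMNS - set(df.columns)
    if missing:
        raise InvalidInputError(f"TrackMate export missing columns: {sorted(missing)}")
    df = df[pd.to_numeric(df["FRAME"], errors="coerce").notna()].copy()
    for col in ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"):
        df[col] = pd.to_numeric(df[col])
    if fps is not None:
        time_s = df["FRAME"] / fps
    elif "POSITION_T" in df.columns:
        time_s = pd.to_numeric(df["POSITION_T"], errors="coerce")
    else:
        raise InvalidInputError("no fps given and no POSITION_T column present")
    out = pd.DataFrame(
        {
            "track_id": df["TRACK_ID"].astype(int),
            "frame": df["FRAME"].astype(int),
            "time_s": time_s.astype(float),
            "x_um": df["POSITION_X"].astype(float),
            "y_um": df["POSITION_Y"].astype(float),
        }
    )
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)
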