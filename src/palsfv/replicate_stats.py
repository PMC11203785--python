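"""Replicate summary statistics for PALS parameters.

Aggregates per-sample (tau3, I3, R, Vf, fv) rows into mean / SD / CV%
summaries, checks normality of replicate measurements with the Shapiro-Wilk
test, and screens per-sample time series for drift.  Two CV bases are
distinguished because they answer different questions: the CV over sample
rows (each already a replicate mean) understates the raw measurement
scatter, while the CV over all individual repetitions reflects it; every
summary records which basis was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryRow",
    "NormalityReport",
    "summarize",
    "normality_check",
    "stability_series",
    "PARAMETER_COLUMNS",
]

#: Canonical numeric columns of a per-sample result row.
PARAMETER_COLUMNS = ("tau3_ns", "i3_percent", "r_nm", "vf_nm3", "fv")


@dataclass(frozen=True)
class SummaryRow:
    """Mean, sample standard deviation (n-1) and CV% of one parameter."""

    parameter: str
    mean: float
    sd: float
    cv_percent: float
    n: int
    basis: str = "rows"


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk normality decision at significance level alpha."""

    statistic: float
    p_value: float
    alpha: float
    normal: bool

    @property
    def decision(self) -> str:
        return "normal" if self.normal else "not normal"


def summarize(
    rows: pd.DataFrame | Sequence[dict],
    columns: Sequence[str] | None = None,
    basis: str = "rows",
) -> pd.DataFrame:
    """Column-wise mean, SD (n-1 denominator) and CV% of replicate rows.

    ``rows`` is a DataFrame (or records) of per-sample results; ``columns``
    defaults to the numeric parameter columns present.  Returns a DataFrame
    indexed by parameter with columns mean, sd, cv_percent, n, basis.
    """
    df = pd.DataFrame(rows)
    if len(df) < 2:
        raise ValueError("at least 2 rows are required for a summary")
    if columns is None:
        columns = [c for c in PARAMETER_COLUMNS if c in df.columns]
        if not columns:
            columns = list(df.select_dtypes("number").columns)
    out = []
    for col in columns:
        values = df[col].to_numpy(dtype=float)
        mean = values.mean()
        sd = values.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        out.append(
            SummaryRow(
                parameter=col,
                mean=float(mean),
                sd=float(sd),
                cv_percent=float(cv),
                n=len(values),
                basis=basis,
            )
        )
    return pd.DataFrame([r.__dict__ for r in out]).set_index("parameter")


def normality_check(
    values: Sequence[float], alpha: float = 0.05
) -> NormalityReport:
    """Shapiro-Wilk test; the null (normality) is retained iff p > alpha.

    Requires 3 <= n <= 5000 and non-constant input.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined normality statistic")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    w, p = stats.shapiro(x)
    return NormalityReport(
        statistic=float(w), p_value=float(p), alpha=alpha, normal=bool(p > alpha)
    )


def stability_series(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-sample drift screen for time-ordered repeat measurements.

    ``measurements`` needs columns sample_id, time_min, tau3_ns, i3_percent
    (one row per repetition).  For each sample and each of tau3 / I3 an
    ordinary least-squares slope versus measurement time is computed with
    its standard error; a sample is flagged for a parameter when |slope|
    exceeds 2 standard errors.  The 2-SE rule is this module's own screen —
    replicate stability is conventionally judged by eye.

    Raises on unordered or duplicate time stamps, or fewer than 3 points
    per sample.
    """
    required = {"sample_id", "time_min", "tau3_ns", "i3_percent"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements lack columns: {sorted(missing)}")
    records = []
    for sample_id, grp in measurements.groupby("sample_id", sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        if len(t) < 3:
            raise ValueError(
                f"sample {sample_id!r}: need >= 3 time points for a trend"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"sample {sample_id!r}: time stamps must be strictly "
                "increasing (no duplicates)"
            )
        for param in ("tau3_ns", "i3_percent"):
            y = grp[param].to_numpy(dtype=float)
            res = stats.linregress(t, y)
            flagged = abs(res.slope) > 2.0 * res.stderr
            records.append(
                {
                    "sample_id": sample_id,
                    "parameter": param,
                    "slope_per_min": float(res.slope),
                    "slope_stderr": float(res.stderr),
                    "flagged": bool(flagged),
                }
            )
    return pd.DataFrame(records)
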