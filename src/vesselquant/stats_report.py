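"""Condition-level statistics: one-way ANOVA with significance stars,
Tukey-fence outlier flagging (flag, never exclude) and summary tables."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSample",
    "AnovaResult",
    "one_way_anova",
    "p_to_stars",
    "flag_outliers",
    "summarize_conditions",
]


@dataclass
class ConditionSample:
    condition: str
    values: np.ndarray    # one value per device

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a condition sample needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    stars: str
    zero_variance: bool = False


def p_to_stars(p: float) -> str:
    """Caption convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def one_way_anova(groups: list[ConditionSample]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.condition!r} has n < 2")
    arrays = [g.values for g in groups]
    pooled = np.concatenate(arrays)
    df_b = len(groups) - 1
    df_w = pooled.size - len(groups)
    if np.allclose(pooled, pooled[0]):
        return AnovaResult(0.0, df_b, df_w, 1.0, "", zero_variance=True)
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), df_b, df_w, float(p), p_to_stars(float(p)))


def flag_outliers(sample: ConditionSample, iqr_factor: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside [Q1 - f*IQR, Q3 + f*IQR].

    Flagged values are reported, never removed.  With n < 4 the fence is
    meaningless; a warning is raised and nothing is flagged.
    """
    v = sample.values
    if v.size < 4:
        warnings.warn(
            f"{sample.condition!r}: n={v.size} < 4, outlier fence not applied",
            stacklevel=2,
        )
        return np.zeros(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - iqr_factor * iqr) | (v > q3 + iqr_factor * iqr)


def summarize_conditions(
    samples: list[ConditionSample],
    iqr_factor: float = 1.5,
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-condition summary plus a pairwise ANOVA star matrix.

    Returns ``(summary table, pairwise dict)`` and optionally writes CSV
    and JSON artifacts.
    """
    if not samples:
        raise ValueError("need at least one condition sample")
    rows = []
    for s in samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = flag_outliers(s, iqr_factor)
        rows.append({
            "condition": s.condition,
            "n": int(s.values.size),
            "mean": float(s.values.mean()),
            "median": float(np.median(s.values)),
            "min": float(s.values.min()),
            "max": float(s.values.max()),
            "n_outliers": int(flags.sum()),
        })
    table = pd.DataFrame(rows)

    pairwise = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            if a.values.size < 2 or b.values.size < 2:
                continue
            res = one_way_anova([a, b])
            pairwise[f"{a.condition} vs {b.condition}"] = {
                "F": res.f_statistic,
                "df": [res.df_between, res.df_within],
                "p": res.p_value,
                "stars": res.stars,
            }

    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump({"conditions": rows, "pairwise_anova": pairwise}, fh, indent=2)
    return table, pairwise
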