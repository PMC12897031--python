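"""Differential abundance statistics and significance classification.

Testing follows the study's scheme: a classical two-sample pooled-variance
(Student) t-test on log2-transformed values, fold change as the ratio of
linear-scale group means, and classification by nominal p < 0.05 combined
with |log2FC| > 0.585 (fold change > 1.5).  Benjamini-Hochberg adjusted
p-values are reported alongside but do not drive the classification — the
study's explicit, exploratory choice.  Features quantified in only one
group cannot be tested and are reported separately as presence/absence
candidates rather than counted as up/down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import SampleDesign

ALPHA = 0.05
FC_RATIO = 1.5

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NS = "ns"


def fold_change_threshold(ratio: float = FC_RATIO) -> float:
    """log2 of a fold-change ratio; log2(1.5) = 0.585 to three decimals."""
    return math.log2(ratio)


FC_THRESHOLD = round(fold_change_threshold(FC_RATIO), 3)  # 0.585 as printed


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero pooled variance with unequal means


def pooled_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sample pooled-variance t-test, two-sided.

    Zero pooled variance with equal means yields t = 0, p = 1; with unequal
    means the difference is infinitely significant relative to the observed
    spread, so p underflows to the smallest positive float and the result
    is flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df,
                           float(np.finfo(float).tiny), degenerate=True)
    t = diff / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, min(p, 1.0))


def classify(log2fc: float, p: float, alpha: float = ALPHA,
             fc_threshold: float = FC_THRESHOLD) -> str:
    """up / down / ns with strict thresholds (p < alpha, |log2FC| > threshold)."""
    if not (math.isfinite(log2fc) and math.isfinite(p)):
        raise ValueError("classify needs finite log2fc and p")
    if p < alpha and log2fc > fc_threshold:
        return CLASS_UP
    if p < alpha and log2fc < -fc_threshold:
        return CLASS_DOWN
    return CLASS_NS


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_analysis(values: pd.DataFrame, design: SampleDesign,
                          alpha: float = ALPHA,
                          fc_threshold: float = FC_THRESHOLD,
                          min_per_group: int = 2
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature t-test and classification on a linear-scale matrix.

    Returns ``(records, untestable)``.  ``records`` carries one row per
    testable feature: linear group means, log2 fold change
    (treatment over reference), pooled-t p-value, BH-adjusted p and class.
    ``untestable`` lists features with fewer than ``min_per_group`` valid
    values in either group, annotated with the group they are present in
    (presence/absence candidates).
    """
    ref_group, trt_group = design.group_names
    ref_cols = design.samples_in(ref_group)
    trt_cols = design.samples_in(trt_group)

    rows = []
    untestable = []
    for fid, row in values.iterrows():
        a = row[ref_cols].dropna().to_numpy(dtype=float)
        b = row[trt_cols].dropna().to_numpy(dtype=float)
        if a.size < min_per_group or b.size < min_per_group:
            present_in = (ref_group if a.size > b.size
                          else trt_group if b.size > a.size else "neither")
            untestable.append((fid, a.size, b.size, present_in))
            continue
        res = pooled_t_test(np.log2(b), np.log2(a))  # treatment vs reference
        mean_ref, mean_trt = float(a.mean()), float(b.mean())
        log2fc = math.log2(mean_trt / mean_ref)
        rows.append({
            "feature": fid,
            f"mean_{ref_group}": mean_ref,
            f"mean_{trt_group}": mean_trt,
            "log2fc": log2fc,
            "t": res.t,
            "p_value": res.p,
            "degenerate": res.degenerate,
            f"n_{ref_group}": a.size,
            f"n_{trt_group}": b.size,
        })

    records = pd.DataFrame(rows)
    if len(records):
        records["bh_adjusted_p"] = bh_adjust(records["p_value"].to_numpy())
        records["class"] = [classify(fc, p, alpha, fc_threshold)
                            for fc, p in zip(records["log2fc"], records["p_value"])]
        records = records.set_index("feature")
    untestable_df = pd.DataFrame(
        untestable, columns=["feature", f"n_{ref_group}", f"n_{trt_group}", "present_in"])
    return records, untestable_df
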