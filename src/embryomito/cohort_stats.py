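"""Group comparisons and per-age summaries of relative mtDNA quantities.

Cohort comparisons (younger vs older mothers, euploid vs aneuploid,
implanted vs not) use unpaired two-tailed t-tests on the relative-quantity
values. Welch's variant is the default because group variances are rarely
equal on this scale; the pooled-variance variant is available. An optional
log2 transform is exposed since RQ values are strongly right-skewed. No
multiple-testing correction is applied across comparisons.

The age boundary separating "younger" and "older" mothers defaults to 38
years (younger: <= 37, older: >= 38).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import EmbryoRecord, Ploidy

DEFAULT_AGE_BOUNDARY = 38


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_two_tailed: float


def split_by_age(
    records: Sequence[EmbryoRecord], boundary: int = DEFAULT_AGE_BOUNDARY
) -> tuple[list[EmbryoRecord], list[EmbryoRecord]]:
    """Partition records into younger (age <= boundary-1) and older
    (age >= boundary) maternal-age groups."""
    younger = [r for r in records if r.maternal_age <= boundary - 1]
    older = [r for r in records if r.maternal_age >= boundary]
    return younger, older


def t_test_unpaired(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "welch",
    log_transform: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of values.

    ``variant`` selects Welch (unequal variances, Welch-Satterthwaite
    degrees of freedom) or the classical pooled-variance test. When both
    groups have zero variance and equal means, t = 0 and p = 1 by
    convention.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ta, tb = (np.log2(a), np.log2(b)) if log_transform else (a, b)
    if ta.var(ddof=1) == 0 and tb.var(ddof=1) == 0:
        equal = ta.mean() == tb.mean()
        t_stat, p, df = (0.0, 1.0, float(len(a) + len(b) - 2)) if equal else (
            float("inf"), 0.0, float(len(a) + len(b) - 2)
        )
    else:
        res = stats.ttest_ind(ta, tb, equal_var=(variant == "pooled"))
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=mean_a,
        mean_b=mean_b,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_two_tailed=p,
    )


def compare_groups(
    records: Sequence[EmbryoRecord],
    rq: dict[str, float],
    by: str,
    variant: str = "welch",
    log_transform: bool = False,
    age_boundary: int = DEFAULT_AGE_BOUNDARY,
) -> GroupComparison:
    """Compare RQ values between cohort groups defined by ``by``:
    ``age`` (younger vs older), ``ploidy`` (euploid vs aneuploid) or
    ``outcome`` (implanted vs not implanted)."""
    if by == "age":
        younger, older = split_by_age(records, age_boundary)
        groups = (younger, older, "younger", "older")
    elif by == "ploidy":
        eu = [r for r in records if r.ploidy is Ploidy.EUPLOID]
        an = [r for r in records if r.ploidy is not Ploidy.EUPLOID]
        groups = (eu, an, "euploid", "aneuploid")
    elif by == "outcome":
        imp = [r for r in records if r.outcome.value == "implanted"]
        non = [r for r in records if r.outcome.value == "not_implanted"]
        groups = (imp, non, "implanted", "not_implanted")
    else:
        raise ValueError(f"unknown grouping {by!r}")
    ga, gb, la, lb = groups
    va = [rq[r.embryo_id] for r in ga if r.embryo_id in rq]
    vb = [rq[r.embryo_id] for r in gb if r.embryo_id in rq]
    return t_test_unpaired(va, vb, variant, log_transform, la, lb)


def summarize_by_age(
    records: Sequence[EmbryoRecord], rq: dict[str, float]
) -> pd.DataFrame:
    """Per-age summary rows: counts, RQ range and mean per ploidy group.

    Ages with a single embryo in a group report the value as the range and
    NaN for the mean (no average is meaningful for n = 1).
    """
    rows = []
    ages = sorted({r.maternal_age for r in records})
    for age in ages:
        at_age = [r for r in records if r.maternal_age == age]
        row: dict = {"age": age}
        for ploidy, tag in ((Ploidy.EUPLOID, "euploid"), (Ploidy.ANEUPLOID, "aneuploid")):
            vals = [
                rq[r.embryo_id]
                for r in at_age
                if r.ploidy is ploidy and r.embryo_id in rq
            ]
            row[f"n_{tag}"] = len(vals)
            row[f"min_{tag}"] = min(vals) if vals else np.nan
            row[f"max_{tag}"] = max(vals) if vals else np.nan
            row[f"mean_{tag}"] = float(np.mean(vals)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
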