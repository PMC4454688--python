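"""Mitochondrial DNA quantification and heteroplasmy from sequencing data.

The sequencing analogue of the qPCR relative quantity is the fraction of
aligned bases falling on the mitochondrial genome, reported as a percent of
the mitochondrial-plus-nuclear total. Because the overwhelming majority of
fragments derive from the nuclear genome, the nuclear base count acts as a
built-in control for the number of cells in the biopsy. Samples above a
viability cutoff (default 0.07%) are classified high/abnormal.

Per-site heteroplasmy is estimated from position-resolved pileup counts on
the 16.6 kb circular mitochondrial genome (positions 1..16569, handled
linearly): the alternate-allele fraction alt/(alt+ref) at sites with
sufficient depth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MT_GENOME_LENGTH = 16_569
DEFAULT_NGS_THRESHOLD_PERCENT = 0.07
DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_FRACTION = 0.05


class NgsClass(str, enum.Enum):
    LOW_NORMAL = "low_normal"
    HIGH_ABNORMAL = "high_abnormal"


@dataclass
class MitoQuant:
    embryo_id: str
    mito_bases: float
    nuclear_bases: float
    fraction_percent: float
    ngs_class: NgsClass


@dataclass
class MitoPileup:
    """Per-position reference/alternate base counts for one sample."""

    embryo_id: str
    positions: np.ndarray  # 1-based mitochondrial coordinates
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        ref = np.asarray(self.ref_count, dtype=int)
        alt = np.asarray(self.alt_count, dtype=int)
        if not (len(pos) == len(ref) == len(alt)):
            raise ValueError("pileup arrays must have equal length")
        if ((pos < 1) | (pos > MT_GENOME_LENGTH)).any():
            raise ValueError(
                f"positions must lie in 1..{MT_GENOME_LENGTH}"
            )
        if (ref < 0).any() or (alt < 0).any():
            raise ValueError("counts must be non-negative")
        self.positions, self.ref_count, self.alt_count = pos, ref, alt


@dataclass
class HeteroplasmyCall:
    position: int
    fraction: float
    depth: int
    status: str  # "heteroplasmic" | "homoplasmic_alt"


def mito_fraction(
    mito_bases: float,
    nuclear_bases: float,
    embryo_id: str = "",
    threshold: float = DEFAULT_NGS_THRESHOLD_PERCENT,
) -> MitoQuant:
    """Percent of aligned bases on the mitochondrial genome.

    fraction_percent = 100 * mito / (mito + nuclear); scale-invariant in the
    total amount of sequencing.
    """
    if mito_bases < 0 or nuclear_bases < 0:
        raise ValueError("base counts must be non-negative")
    total = mito_bases + nuclear_bases
    if total <= 0:
        raise ValueError(f"{embryo_id}: no aligned bases")
    percent = 100.0 * mito_bases / total
    return MitoQuant(
        embryo_id=embryo_id,
        mito_bases=mito_bases,
        nuclear_bases=nuclear_bases,
        fraction_percent=percent,
        ngs_class=classify_ngs(percent, threshold),
    )


def classify_ngs(
    fraction_percent: float, threshold: float = DEFAULT_NGS_THRESHOLD_PERCENT
) -> NgsClass:
    """Classify a mito percent against the viability cutoff (strict >)."""
    if not 0.0 <= fraction_percent <= 100.0:
        raise ValueError(f"fraction_percent must be in [0, 100], got {fraction_percent}")
    return NgsClass.HIGH_ABNORMAL if fraction_percent > threshold else NgsClass.LOW_NORMAL


def heteroplasmy_calls(
    pileup: MitoPileup,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list[HeteroplasmyCall]:
    """Report non-reference sites from a pileup.

    Sites with depth >= ``min_depth`` and alternate fraction in
    [min_fraction, 1 - min_fraction] are heteroplasmic; fractions above
    1 - min_fraction are homoplasmic for the alternate allele. Sites below
    ``min_fraction`` (homoplasmic reference) are not listed.
    """
    if not 0 < min_fraction < 0.5:
        raise ValueError("min_fraction must lie in (0, 0.5)")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    calls = []
    depth = pileup.ref_count + pileup.alt_count
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, pileup.alt_count / np.maximum(depth, 1), 0.0)
    for pos, f, d in zip(pileup.positions, frac, depth):
        if d < min_depth or f < min_fraction:
            continue
        status = "heteroplasmic" if f <= 1.0 - min_fraction else "homoplasmic_alt"
        calls.append(HeteroplasmyCall(int(pos), float(f), int(d), status))
    return calls


def mutation_load_compare(
    group_high: list[list[HeteroplasmyCall]],
    group_low: list[list[HeteroplasmyCall]],
) -> dict:
    """Compare per-sample heteroplasmic-site counts between two groups.

    Counts heteroplasmic sites per sample in each group and compares group
    means with an unpaired two-tailed Welch t-test. With fewer than two
    samples in either group the comparison is skipped (p reported as NaN).
    """
    if not group_high or not group_low:
        raise ValueError("both groups must be non-empty")
    counts_high = [sum(c.status == "heteroplasmic" for c in calls) for calls in group_high]
    counts_low = [sum(c.status == "heteroplasmic" for c in calls) for calls in group_low]
    result = {
        "counts_high": counts_high,
        "counts_low": counts_low,
        "mean_high": float(np.mean(counts_high)),
        "mean_low": float(np.mean(counts_low)),
        "p_two_tailed": float("nan"),
    }
    if len(counts_high) < 2 or len(counts_low) < 2:
        result["warning"] = "group of size < 2; comparison skipped"
        return result
    if np.var(counts_high) == 0 and np.var(counts_low) == 0:
        result["p_two_tailed"] = 1.0 if result["mean_high"] == result["mean_low"] else 0.0
        return result
    t = stats.ttest_ind(counts_high, counts_low, equal_var=False)
    result["p_two_tailed"] = float(t.pvalue)
    return result


def quantify_base_counts(
    table: pd.DataFrame, threshold: float = DEFAULT_NGS_THRESHOLD_PERCENT
) -> pd.DataFrame:
    """Quantify a base-count summary table (embryo_id, mito_bases,
    nuclear_bases) into per-sample mito percents and classes."""
    required = {"embryo_id", "mito_bases", "nuclear_bases"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"base-count table missing columns: {sorted(missing)}")
    rows = []
    for _, row in table.iterrows():
        q = mito_fraction(
            row["mito_bases"], row["nuclear_bases"], str(row["embryo_id"]), threshold
        )
        rows.append(
            {
                "embryo_id": q.embryo_id,
                "mito_bases": q.mito_bases,
                "nuclear_bases": q.nuclear_bases,
                "fraction_percent": q.fraction_percent,
                "class": q.ngs_class.value,
            }
        )
    return pd.DataFrame(rows)
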