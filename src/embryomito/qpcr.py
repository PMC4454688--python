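"""Relative quantification of mtDNA from real-time PCR cycle thresholds.

The relative quantity (RQ) of mitochondrial DNA is computed by the 2^-ddCt
method: triplicate Ct values for a mitochondrial target and for the
multicopy nuclear Alu target are averaged, dCt = Ct_mt - Ct_alu is formed
for the test sample, and ddCt = dCt_test - dCt_reference subtracts the dCt
of a constant reference sample measured in the same assay system. RQ =
2^-ddCt, so one PCR cycle corresponds to a factor of two. Amplification
efficiency is assumed to be exactly 2 per cycle; no efficiency correction
is applied.

Samples with RQ above a viability-associated cutoff (default 0.003) are
classified as high/abnormal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_QPCR_THRESHOLD = 0.003
DEFAULT_MAX_REPLICATE_SD = 0.5
CT_CAP = 40.0


class Assay(str, enum.Enum):
    MT = "mt"
    ALU = "alu"


class QcFlag(str, enum.Enum):
    PASS = "pass"
    HIGH_REPLICATE_SD = "high_replicate_sd"


class QpcrClass(str, enum.Enum):
    LOW_NORMAL = "low_normal"
    HIGH_ABNORMAL = "high_abnormal"


@dataclass
class CtTriplicate:
    """Three replicate cycle-threshold values for one assay on one sample."""

    embryo_id: str
    assay: Assay
    ct_values: tuple[float, float, float]
    ct_cap: float = CT_CAP

    def __post_init__(self) -> None:
        if isinstance(self.assay, str):
            self.assay = Assay(self.assay)
        vals = tuple(float(v) for v in self.ct_values)
        if len(vals) != 3:
            raise ValueError(
                f"{self.embryo_id}/{self.assay.value}: exactly 3 replicates "
                f"required, got {len(vals)}"
            )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(
                f"{self.embryo_id}/{self.assay.value}: missing or non-finite "
                "replicate (no imputation is performed)"
            )
        if not all(0.0 < v <= self.ct_cap for v in vals):
            raise ValueError(
                f"{self.embryo_id}/{self.assay.value}: Ct values must lie in "
                f"(0, {self.ct_cap}]"
            )
        self.ct_values = vals


@dataclass
class RelativeQuantity:
    """Derived 2^-ddCt statistic for one sample."""

    embryo_id: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    qc_flag: QcFlag = QcFlag.PASS


def aggregate_triplicates(
    triplicate: CtTriplicate, max_sd: float = DEFAULT_MAX_REPLICATE_SD
) -> tuple[float, QcFlag]:
    """Mean Ct of a triplicate with a replicate-scatter QC flag.

    The sample standard deviation (ddof=1) across the three replicates is
    compared against ``max_sd`` (cycles); scattered triplicates are flagged
    but still quantified downstream.
    """
    values = np.asarray(triplicate.ct_values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    flag = QcFlag.HIGH_REPLICATE_SD if sd > max_sd else QcFlag.PASS
    return mean, flag


def delta_ct(ct_mt_mean: float, ct_alu_mean: float) -> float:
    """dCt = mean mitochondrial Ct minus mean Alu Ct."""
    if not (math.isfinite(ct_mt_mean) and math.isfinite(ct_alu_mean)):
        raise ValueError("Ct means must be finite")
    return ct_mt_mean - ct_alu_mean


def relative_quantity(
    delta_ct_test: float,
    delta_ct_reference: float,
    embryo_id: str = "",
    qc_flag: QcFlag = QcFlag.PASS,
) -> RelativeQuantity:
    """2^-ddCt relative quantity against a run-constant reference sample.

    ``delta_ct_reference`` is the reference sample's dCt; its negative is
    the normalisation factor added to each test dCt.
    """
    if not (math.isfinite(delta_ct_test) and math.isfinite(delta_ct_reference)):
        raise ValueError("dCt inputs must be finite")
    ddct = delta_ct_test - delta_ct_reference
    return RelativeQuantity(
        embryo_id=embryo_id,
        delta_ct=delta_ct_test,
        delta_delta_ct=ddct,
        rq=2.0 ** (-ddct),
        qc_flag=qc_flag,
    )


def classify_qpcr(rq: float, threshold: float = DEFAULT_QPCR_THRESHOLD) -> QpcrClass:
    """Classify an RQ value against the viability cutoff (strict >)."""
    if not rq > 0:
        raise ValueError(f"rq must be positive, got {rq}")
    return QpcrClass.HIGH_ABNORMAL if rq > threshold else QpcrClass.LOW_NORMAL


def quantify_sample(
    mt: CtTriplicate,
    alu: CtTriplicate,
    reference_delta_ct: float,
    max_sd: float = DEFAULT_MAX_REPLICATE_SD,
) -> RelativeQuantity:
    """Full per-sample quantification: aggregate, dCt, ddCt, RQ.

    The QC flag is raised if either assay's triplicate scatters beyond
    ``max_sd``.
    """
    if mt.embryo_id != alu.embryo_id:
        raise ValueError(
            f"assay triplicates belong to different samples: "
            f"{mt.embryo_id!r} vs {alu.embryo_id!r}"
        )
    mt_mean, mt_flag = aggregate_triplicates(mt, max_sd)
    alu_mean, alu_flag = aggregate_triplicates(alu, max_sd)
    flag = (
        QcFlag.HIGH_REPLICATE_SD
        if QcFlag.HIGH_REPLICATE_SD in (mt_flag, alu_flag)
        else QcFlag.PASS
    )
    dct = delta_ct(mt_mean, alu_mean)
    return relative_quantity(dct, reference_delta_ct, mt.embryo_id, flag)


def quantify_ct_table(
    ct_table: pd.DataFrame,
    reference_delta_ct: float,
    threshold: float = DEFAULT_QPCR_THRESHOLD,
    max_sd: float = DEFAULT_MAX_REPLICATE_SD,
) -> pd.DataFrame:
    """Quantify every sample in a long-format Ct table.

    Expects columns ``embryo_id``, ``assay`` (``mt``/``alu``) and
    ``rep1..rep3``; returns one row per embryo with dCt, ddCt, RQ, QC flag
    and class.
    """
    required = {"embryo_id", "assay", "rep1", "rep2", "rep3"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for embryo_id, group in ct_table.groupby("embryo_id", sort=False):
        trips = {}
        for _, row in group.iterrows():
            trips[row["assay"]] = CtTriplicate(
                embryo_id=str(embryo_id),
                assay=row["assay"],
                ct_values=(row["rep1"], row["rep2"], row["rep3"]),
            )
        if set(trips) != {Assay.MT, Assay.ALU}:
            raise ValueError(
                f"{embryo_id}: need exactly one mt and one alu triplicate"
            )
        quant = quantify_sample(
            trips[Assay.MT], trips[Assay.ALU], reference_delta_ct, max_sd
        )
        rows.append(
            {
                "embryo_id": quant.embryo_id,
                "delta_ct": quant.delta_ct,
                "delta_delta_ct": quant.delta_delta_ct,
                "rq": quant.rq,
                "qc_flag": quant.qc_flag.value,
                "class": classify_qpcr(quant.rq, threshold).value,
            }
        )
    return pd.DataFrame(rows)
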