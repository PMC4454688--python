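"""Shared readers and writers for the pipeline's plain-text formats.

Interchange formats are CSV/TSV with header rows (sample sheets, Ct
tables, bin grids, bin counts, pileups) and JSON for models and metrics.
Numbers are written at full precision; rounding happens only in displayed
reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cnv import BinCountVector, BinGrid
from .mito import MitoPileup
from .qpcr import CtTriplicate
from .records import EmbryoRecord, Outcome, Ploidy, Stage
from .viability import CohortMetrics, ThresholdModel

SAMPLE_SHEET_COLUMNS = ["embryo_id", "maternal_age", "stage", "ploidy", "outcome"]


def write_sample_sheet(records: Sequence[EmbryoRecord], path) -> None:
    rows = [
        {
            "embryo_id": r.embryo_id,
            "maternal_age": r.maternal_age,
            "stage": r.stage.value,
            "ploidy": r.ploidy.value,
            "outcome": r.outcome.value,
            "true_mt_rq": r.true_mt_rq,
            "true_mt_fraction": r.true_mt_fraction,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sample_sheet(path) -> list[EmbryoRecord]:
    """Load and validate a sample-sheet CSV into embryo records.

    Requires the columns embryo_id, maternal_age, stage, ploidy, outcome;
    unknown columns are preserved on the frame but ignored here. Duplicate
    embryo ids are an error; ages outside 18-50 raise a warning only.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(
            f"{path}: empty file; expected columns {SAMPLE_SHEET_COLUMNS}"
        ) from None
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dupes = df["embryo_id"][df["embryo_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate embryo_id: {list(dupes)}")
    records = []
    for _, row in df.iterrows():
        age = int(row["maternal_age"])
        if not 18 <= age <= 50:
            warnings.warn(
                f"{row['embryo_id']}: maternal age {age} outside 18-50", stacklevel=2
            )
        records.append(
            EmbryoRecord(
                embryo_id=str(row["embryo_id"]),
                maternal_age=age,
                stage=Stage(row["stage"]),
                ploidy=Ploidy(row["ploidy"]),
                aneuploid_chromosomes=(
                    [] if Ploidy(row["ploidy"]) is Ploidy.EUPLOID else [("unknown", 3)]
                ),
                outcome=Outcome(row["outcome"]),
                true_mt_rq=float(row.get("true_mt_rq", float("nan"))),
                true_mt_fraction=float(row.get("true_mt_fraction", float("nan"))),
            )
        )
    return records


def write_ct_table(triplicates: Sequence[CtTriplicate], path) -> None:
    rows = [
        {
            "embryo_id": t.embryo_id,
            "assay": t.assay.value,
            "rep1": t.ct_values[0],
            "rep2": t.ct_values[1],
            "rep3": t.ct_values[2],
        }
        for t in triplicates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bin_counts(counts: Sequence[BinCountVector], grid: BinGrid, path) -> None:
    """Bin-count TSV keyed to the grid: one chrom/start/end block plus one
    raw-count column per embryo."""
    df = grid.bins[["chrom", "start", "end"]].copy()
    for c in counts:
        df[c.embryo_id] = c.raw_count
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path, grid: BinGrid) -> list[BinCountVector]:
    df = pd.read_csv(path, sep="\t")
    if len(df) != len(grid):
        raise ValueError("count table length does not match the grid")
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return [
        BinCountVector(embryo_id=c, raw_count=df[c].to_numpy()) for c in sample_cols
    ]


def write_pileup(pileup: MitoPileup, path) -> None:
    pd.DataFrame(
        {
            "position": pileup.positions,
            "ref_count": pileup.ref_count,
            "alt_count": pileup.alt_count,
        }
    ).to_csv(path, sep="\t", index=False)


def read_pileup(path, embryo_id: str = "") -> MitoPileup:
    df = pd.read_csv(path, sep="\t")
    return MitoPileup(
        embryo_id=embryo_id,
        positions=df["position"].to_numpy(),
        ref_count=df["ref_count"].to_numpy(),
        alt_count=df["alt_count"].to_numpy(),
    )


def write_threshold(model: ThresholdModel, path) -> None:
    Path(path).write_text(json.dumps(asdict(model), indent=2) + "\n")


def write_metrics(metrics: CohortMetrics, path) -> None:
    Path(path).write_text(json.dumps(asdict(metrics), indent=2) + "\n")
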