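"""Whole-chromosome copy-number calling from binned shallow-sequencing depth.

The genome is divided into non-overlapping bins of fixed unique-mappability
content (canonically 100 uniquely mapping 36-mers per bin). Filtered reads
are counted per bin, counts are normalised for GC bias (1%-GC-stratum median
ratio) and for a per-bin in-silico reference weight, and converted to copy
number by

    CN_i = normalized_count_i / median(normalized autosomal counts) * 2

so the autosomal median corresponds to the diploid state by construction.
Bin-wise copy numbers are smoothed with a 13-bin sliding median that never
crosses a chromosome boundary, and each chromosome is called from the median
of its smoothed values (gain >= 2.5 copies, loss <= 1.5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gc_fraction",
    "mappable_36mers",
    "reference_weight",
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

DEFAULT_WINDOW = 13
DEFAULT_GAIN_CUTOFF = 2.5
DEFAULT_LOSS_CUTOFF = 1.5


def is_autosome(chrom: str) -> bool:
    return chrom not in SEX_CHROMOSOMES


@dataclass
class BinGrid:
    """Ordered genomic bins with GC fraction and in-silico reference weight.

    Coordinates are 0-based half-open (BED convention). Bins must be sorted
    by (chromosome, start) and non-overlapping within a chromosome;
    ``reference_weight`` encodes the expected relative depth of each bin in
    an in-silico reference set, normalised to median 1.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(GRID_COLUMNS) - set(self.bins.columns)
        if missing:
            raise ValueError(f"grid missing columns: {sorted(missing)}")
        if len(self.bins) == 0:
            raise ValueError("empty bin grid")
        df = self.bins.reset_index(drop=True)
        if ((df["end"] <= df["start"]).any()):
            raise ValueError("bins must have end > start")
        if not df["gc_fraction"].between(0, 1).all():
            raise ValueError("gc_fraction must lie in [0, 1]")
        if (df["reference_weight"] <= 0).any():
            raise ValueError("reference_weight must be positive")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"{chrom}: bins overlap or are unsorted")
        self.bins = df

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def autosomal_mask(self) -> np.ndarray:
        return self.bins["chrom"].map(is_autosome).to_numpy(dtype=bool)

    @classmethod
    def read_tsv(cls, path) -> "BinGrid":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


@dataclass
class AlignmentSummary:
    """Minimal per-read alignment summary used by the filtering step."""

    chrom: str
    position: int
    mapped: bool = True
    duplicate: bool = False
    mapping_score: int = 60
    mismatches: int = 0


@dataclass
class BinCountVector:
    """Raw and (optionally) normalised per-bin read counts for one sample."""

    embryo_id: str
    raw_count: np.ndarray
    normalized_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_count)
        if (raw < 0).any():
            raise ValueError("raw counts must be non-negative")
        self.raw_count = raw

    def counts(self) -> np.ndarray:
        """Normalised counts when available, raw otherwise (as float)."""
        if self.normalized_count is not None:
            return np.asarray(self.normalized_count, dtype=float)
        return self.raw_count.astype(float)


@dataclass
class ChromosomeCall:
    chrom: str
    median_cn: float
    state: str  # "loss" | "neutral" | "gain" | "not_called"
    n_bins: int = 0


@dataclass
class CopyNumberProfile:
    """Per-bin copy numbers, their smoothed version, and chromosome calls."""

    embryo_id: str
    grid: BinGrid
    cn: np.ndarray
    smoothed_cn: np.ndarray | None = None
    calls: list[ChromosomeCall] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        states = {c.state for c in self.calls}
        return "aneuploid" if states & {"gain", "loss"} else "euploid"


def filter_alignments(
    records: Iterable[AlignmentSummary],
    min_mapping_score: int = 20,
    max_mismatches: int = 1,
) -> Iterator[AlignmentSummary]:
    """Keep mapped, non-duplicate reads with adequate mapping score and at
    most ``max_mismatches`` mismatches against the reference."""
    for rec in records:
        if not rec.mapped or rec.duplicate:
            continue
        if rec.mapping_score < min_mapping_score:
            continue
        if rec.mismatches > max_mismatches:
            continue
        yield rec


def count_reads_per_bin(
    records: Iterable[AlignmentSummary], grid: BinGrid, embryo_id: str = ""
) -> BinCountVector:
    """Assign each read to the bin whose half-open interval contains its
    start position; reads outside every bin are dropped and tallied."""
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in grid.bins.groupby("chrom", sort=False):
        index[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )
    counts = np.zeros(len(grid), dtype=np.int64)
    dropped = 0
    for rec in records:
        entry = index.get(rec.chrom)
        if entry is None:
            dropped += 1
            continue
        starts, ends, idx = entry
        j = int(np.searchsorted(starts, rec.position, side="right")) - 1
        if j >= 0 and rec.position < ends[j]:
            counts[idx[j]] += 1
        else:
            dropped += 1
    if dropped:
        logger.info("count_reads_per_bin: %d reads outside the grid dropped", dropped)
    return BinCountVector(embryo_id=embryo_id, raw_count=counts)


def _gc_strata(gc: np.ndarray, min_bins: int) -> np.ndarray:
    """Map each bin to a GC stratum label: 1% GC bands, adjacent bands merged
    left-to-right until every stratum holds at least ``min_bins`` bins."""
    raw = np.floor(np.clip(gc, 0.0, 0.9999) * 100).astype(int)
    order = np.unique(raw)
    sizes = {s: int((raw == s).sum()) for s in order}
    groups: list[list[int]] = []
    current: list[int] = []
    size = 0
    for s in order:
        current.append(s)
        size += sizes[s]
        if size >= min_bins:
            groups.append(current)
            current, size = [], 0
    if current:  # small tail merges into the last full stratum
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    label = {s: group[0] for group in groups for s in group}
    return np.array([label[s] for s in raw])


def gc_normalize(
    counts: BinCountVector, grid: BinGrid, min_bins_per_stratum: int = 20
) -> BinCountVector:
    """Remove GC bias and in-silico reference bias from raw bin counts.

    Counts are divided by the ratio of their GC stratum's median to the
    global median (strata are 1% GC bands, merged until each holds at least
    ``min_bins_per_stratum`` bins), then by the per-bin reference weight.
    Stratum medians are estimated on autosomal bins only, so a sample's sex
    chromosomes cannot distort the bias curve. The output is rescaled so
    its autosomal median equals the input autosomal median.
    """
    raw = counts.raw_count.astype(float)
    if len(raw) != len(grid):
        raise ValueError("count vector length does not match the grid")
    if not raw.any():
        raise ValueError(f"{counts.embryo_id}: all bin counts are zero (sample failed)")
    auto = grid.autosomal_mask
    gc = grid.bins["gc_fraction"].to_numpy(dtype=float)
    strata = _gc_strata(gc, min_bins_per_stratum)
    global_median = float(np.median(raw[auto]))
    factors = np.ones_like(raw)
    for s in np.unique(strata):
        members = strata == s
        contributing = members & auto
        if contributing.sum() == 0:
            continue
        med = float(np.median(raw[contributing]))
        if med > 0:
            factors[members] = med / global_median
    normalized = raw / factors / grid.bins["reference_weight"].to_numpy(dtype=float)
    new_median = float(np.median(normalized[auto]))
    if new_median > 0:
        normalized *= global_median / new_median
    return BinCountVector(
        embryo_id=counts.embryo_id, raw_count=counts.raw_count, normalized_count=normalized
    )


def copy_number_per_bin(counts: BinCountVector, grid: BinGrid) -> CopyNumberProfile:
    """Convert (normalised) bin counts to copies via the diploid-median rule."""
    values = counts.counts()
    if len(values) != len(grid):
        raise ValueError("count vector length does not match the grid")
    auto = grid.autosomal_mask
    if not auto.any():
        raise ValueError("grid has no autosomal bin")
    med = float(np.median(values[auto]))
    if med <= 0:
        raise ValueError("zero autosomal median; cannot scale to copy number")
    cn = values / med * 2.0
    return CopyNumberProfile(embryo_id=counts.embryo_id, grid=grid, cn=cn)


def sliding_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding median with symmetric shrinkage at the edges.

    At position i the half-window is ``min(window // 2, i, n - 1 - i)`` so
    edge windows stay centred and no position is discarded.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - h : i + h + 1])
    return out


def smooth_copy_number(
    profile: CopyNumberProfile, window: int = DEFAULT_WINDOW
) -> CopyNumberProfile:
    """Smooth bin-wise copy numbers chromosome by chromosome; the window
    never crosses a chromosome boundary."""
    chroms = profile.grid.bins["chrom"].to_numpy()
    smoothed = np.empty_like(profile.cn, dtype=float)
    for chrom in profile.grid.chromosomes:
        mask = chroms == chrom
        smoothed[mask] = sliding_median(profile.cn[mask], window)
    profile.smoothed_cn = smoothed
    return profile


def call_chromosomes(
    profile: CopyNumberProfile,
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
    sample_sex: str | None = None,
) -> CopyNumberProfile:
    """Call each chromosome from the median of its smoothed copy numbers.

    Autosomes: gain when median >= ``gain_cutoff`` copies, loss when
    <= ``loss_cutoff``. Sex chromosomes are shifted to a diploid-equivalent
    scale using the expected copies for a declared ``sample_sex`` ("XX" or
    "XY"); without a declared sex they are reported uncalled with their raw
    median. The sample verdict is aneuploid iff any chromosome is non-neutral.
    """
    if profile.smoothed_cn is None:
        raise ValueError("profile must be smoothed before calling")
    expected_sex = {"XX": {"chrX": 2.0, "X": 2.0, "chrY": 0.0, "Y": 0.0},
                    "XY": {"chrX": 1.0, "X": 1.0, "chrY": 1.0, "Y": 1.0}}
    chroms = profile.grid.bins["chrom"].to_numpy()
    calls = []
    for chrom in profile.grid.chromosomes:
        mask = chroms == chrom
        if not mask.any():
            raise ValueError(f"{chrom}: no bins")
        m = float(np.median(profile.smoothed_cn[mask]))
        if is_autosome(chrom):
            shifted = m
        elif sample_sex in expected_sex:
            shifted = m - expected_sex[sample_sex][chrom] + 2.0
        else:
            calls.append(ChromosomeCall(chrom, m, "not_called", int(mask.sum())))
            continue
        if shifted >= gain_cutoff:
            state = "gain"
        elif shifted <= loss_cutoff:
            state = "loss"
        else:
            state = "neutral"
        calls.append(ChromosomeCall(chrom, m, state, int(mask.sum())))
    profile.calls = calls
    return profile


def call_profile(
    counts: BinCountVector,
    grid: BinGrid,
    window: int = DEFAULT_WINDOW,
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
    sample_sex: str | None = None,
    normalize: bool = True,
) -> CopyNumberProfile:
    """Run the full per-sample pipeline: normalise, scale, smooth, call."""
    if normalize and counts.normalized_count is None:
        counts = gc_normalize(counts, grid)
    profile = copy_number_per_bin(counts, grid)
    profile = smooth_copy_number(profile, window)
    return call_chromosomes(profile, gain_cutoff, loss_cutoff, sample_sex)


def calls_frame(profile: CopyNumberProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "median_cn": c.median_cn,
                "state": c.state,
                "n_bins": c.n_bins,
            }
            for c in profile.calls
        ]
    )
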