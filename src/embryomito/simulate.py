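"""Synthetic embryo cohorts with the statistical structure the pipeline assumes.

The generator produces, from one global seed, (i) embryo cohorts whose
maternal ages, per-age aneuploidy rates and latent relative mtDNA
quantities follow the structure observed in clinical screening cohorts:
blastocyst mtDNA rising with maternal age, falling with age at the cleavage
stage, elevated in aneuploids, and — among transferred euploid blastocysts —
never above the viability cutoff when implantation succeeded, while a
configurable share (default 30%) of non-implanters lies above it;
(ii) triplicate qPCR cycle thresholds consistent with a planted relative
quantity; (iii) negative-binomial per-bin read counts with a quadratic GC
bias and planted whole-chromosome gains/losses; and (iv) mitochondrial
pileups with planted heteroplasmies.

Latent relative quantities are log-normal: observed per-age ranges span two
orders of magnitude, so multiplicative variation is the simplest consistent
model. The latent sequencing fraction is tied to the latent RQ by a
monotone affine map calibrated so that the paired viability cutoffs
(RQ 0.003 and 0.07% of aligned bases) correspond.

All randomness flows through substreams derived deterministically from the
single config seed, so every generated object is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cnv import BinGrid, BinCountVector, GRID_COLUMNS
from .datasets import default_age_weights, default_aneuploidy_rate_by_age
from .mito import MT_GENOME_LENGTH, MitoPileup
from .qpcr import Assay, CtTriplicate
from .records import EmbryoRecord, Outcome, Ploidy, Stage

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

# substream tags
_S_COHORT = 1
_S_QPCR = 2
_S_BINS = 3
_S_PILEUP = 4
_S_GRID = 5


def _rng(seed: int, tag: int, key: str | int = 0) -> np.random.Generator:
    sub = zlib.crc32(str(key).encode()) if isinstance(key, str) else key
    return np.random.default_rng([seed, tag, sub])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Age effects are multiplicative per year of maternal age on the latent
    RQ (blastocysts > 1, cleavage < 1); ``aneuploidy_effect`` multiplies the
    latent RQ of aneuploid embryos. ``rq_lognormal_sigma`` is the standard
    deviation of the natural-log RQ. ``nonimplanter_elevated_fraction`` is
    the probability that a non-implanting euploid blastocyst has its RQ
    resampled above ``viability_cutoff``.
    """

    n_embryos: int = 302
    stage: Stage = Stage.BLASTOCYST
    age_distribution: dict[int, float] = field(default_factory=default_age_weights)
    aneuploidy_rate_by_age: dict[int, float] = field(
        default_factory=default_aneuploidy_rate_by_age
    )
    blastocyst_age_effect: float = 1.10
    cleavage_age_effect: float = 0.85
    aneuploidy_effect: float = 1.8
    nonimplanter_elevated_fraction: float = 0.30
    viability_cutoff: float = 0.003
    rq_lognormal_sigma: float = 1.0
    baseline_rq: float = 0.0015  # geometric-mean euploid blastocyst RQ at reference_age
    cleavage_baseline_rq: float = 0.05
    reference_age: int = 38
    transfer_fraction: float = 0.44  # euploid blastocysts with a known transfer outcome
    implantation_rate: float = 0.47  # implantation probability once transferred
    ct_noise_sd: float = 0.25  # per-replicate Gaussian Ct noise, cycles
    alu_ct_baseline: float = 20.0
    nb_dispersion: float = 0.1  # NB variance = mu + d*mu^2; 0 gives Poisson
    gc_bias_coefficients: tuple[float, float, float] = (0.2, 4.0, -5.0)
    mean_reads_per_bin: float = 50.0
    error_rate: float = 0.002  # per-base sequencing error in pileups
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.stage, str):
            self.stage = Stage(self.stage)
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")
        if not self.age_distribution:
            raise ValueError("age_distribution must be non-empty")
        for name in (
            "nonimplanter_elevated_fraction",
            "transfer_fraction",
            "implantation_rate",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "blastocyst_age_effect",
            "cleavage_age_effect",
            "aneuploidy_effect",
            "viability_cutoff",
            "baseline_rq",
            "cleavage_baseline_rq",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        if self.rq_lognormal_sigma < 0 or self.ct_noise_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("scale parameters must be non-negative")
        for p in self.aneuploidy_rate_by_age.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("aneuploidy rates must lie in [0, 1]")


# --- latent-quantity model ---------------------------------------------------

def _log_rq_mean(age: int, ploidy: Ploidy, stage: Stage, config: SimulationConfig) -> float:
    if stage is Stage.BLASTOCYST:
        base, effect = config.baseline_rq, config.blastocyst_age_effect
    else:
        base, effect = config.cleavage_baseline_rq, config.cleavage_age_effect
    mu = np.log(base) + (age - config.reference_age) * np.log(effect)
    if ploidy is Ploidy.ANEUPLOID:
        mu += np.log(config.aneuploidy_effect)
    return float(mu)


def _sample_rq(
    rng: np.random.Generator,
    mu: float,
    sigma: float,
    cutoff: float | None = None,
    side: str | None = None,
) -> float:
    """Draw exp(mu + sigma*Z), optionally truncated below/above ``cutoff``."""
    if cutoff is None or sigma == 0:
        value = float(np.exp(mu + sigma * rng.standard_normal()))
        if cutoff is not None:
            # degenerate sigma: fall back to clipping at the cutoff
            value = min(value, cutoff * 0.999) if side == "below" else max(
                value, cutoff * 1.001
            )
        return value
    z_cut = (np.log(cutoff) - mu) / sigma
    p = float(sps.norm.cdf(z_cut))
    p = min(max(p, 1e-12), 1 - 1e-12)
    u = rng.uniform(0.0, p) if side == "below" else rng.uniform(p, 1.0)
    return float(np.exp(mu + sigma * sps.norm.ppf(u)))


def rq_to_fraction_percent(rq: float) -> float:
    """Monotone map from the qPCR RQ scale to the NGS percent scale.

    Affine with a background floor of 0.03% (the mito percent observed for
    the lowest-RQ samples), calibrated so RQ 0.003 maps to exactly 0.07%.
    """
    return min(0.03 + (0.04 / 0.003) * rq, 5.0)


# --- cohort ------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> list[EmbryoRecord]:
    """Generate a cohort of embryos with latent mitochondrial quantities.

    Euploid blastocysts receive a transfer outcome (implanted /
    not_implanted / unknown); aneuploid embryos are never transferred.
    Implanted embryos always carry a latent RQ below the viability cutoff;
    among non-implanters, a fraction ``nonimplanter_elevated_fraction`` is
    resampled above it and the rest below.
    """
    rng = _rng(config.seed, _S_COHORT)
    ages = list(config.age_distribution)
    weights = np.array([config.age_distribution[a] for a in ages], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("age weights must be non-negative and sum to > 0")
    weights = weights / weights.sum()
    overall_rate = float(np.mean(list(config.aneuploidy_rate_by_age.values()) or [0.0]))
    records = []
    for i in range(config.n_embryos):
        age = int(rng.choice(ages, p=weights))
        p_aneu = config.aneuploidy_rate_by_age.get(age, overall_rate)
        aneuploid = rng.uniform() < p_aneu
        aneuploid_chromosomes: list[tuple[str, int]] = []
        if aneuploid:
            chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
            state = 3 if rng.uniform() < 0.5 else 1
            aneuploid_chromosomes = [(chrom, state)]
        ploidy = Ploidy.ANEUPLOID if aneuploid else Ploidy.EUPLOID
        mu = _log_rq_mean(age, ploidy, config.stage, config)
        sigma = config.rq_lognormal_sigma
        outcome = Outcome.UNKNOWN
        if ploidy is Ploidy.EUPLOID and config.stage is Stage.BLASTOCYST:
            if rng.uniform() < config.transfer_fraction:
                outcome = (
                    Outcome.IMPLANTED
                    if rng.uniform() < config.implantation_rate
                    else Outcome.NOT_IMPLANTED
                )
        if outcome is Outcome.IMPLANTED:
            rq = _sample_rq(rng, mu, sigma, config.viability_cutoff, "below")
        elif outcome is Outcome.NOT_IMPLANTED:
            side = (
                "above"
                if rng.uniform() < config.nonimplanter_elevated_fraction
                else "below"
            )
            rq = _sample_rq(rng, mu, sigma, config.viability_cutoff, side)
        else:
            rq = _sample_rq(rng, mu, sigma)
        records.append(
            EmbryoRecord(
                embryo_id=f"E{i + 1:04d}",
                maternal_age=age,
                stage=config.stage,
                ploidy=ploidy,
                aneuploid_chromosomes=aneuploid_chromosomes,
                outcome=outcome,
                true_mt_rq=rq,
                true_mt_fraction=rq_to_fraction_percent(rq) / 100.0,
            )
        )
    return records


# --- qPCR --------------------------------------------------------------------

def simulate_qpcr(
    record: EmbryoRecord,
    config: SimulationConfig,
    reference_delta_ct: float = 5.0,
) -> tuple[CtTriplicate, CtTriplicate]:
    """Triplicate Ct values for the mitochondrial and Alu assays.

    The Alu triplicate centres on a fixed baseline (plus a sample-level
    shift that cancels exactly in dCt); the mitochondrial centre is
    Ct_alu + reference dCt - log2(true RQ), so noise-free quantification
    recovers the planted RQ exactly. Each replicate is perturbed by
    independent Gaussian noise with sd ``ct_noise_sd``.
    """
    if not record.true_mt_rq > 0:
        raise ValueError(f"{record.embryo_id}: true_mt_rq must be positive")
    rng = _rng(config.seed, _S_QPCR, record.embryo_id)
    sample_shift = 2.0 * config.ct_noise_sd * rng.standard_normal()
    alu_center = config.alu_ct_baseline + sample_shift
    mt_center = alu_center + reference_delta_ct - np.log2(record.true_mt_rq)
    alu_vals = alu_center + config.ct_noise_sd * rng.standard_normal(3)
    mt_vals = mt_center + config.ct_noise_sd * rng.standard_normal(3)
    # ideal (uncapped) cycle thresholds: the instrument cap applies to real
    # data ingestion, not to the generative model, so tiny planted RQs stay
    # exactly recoverable
    cap = float("inf")
    return (
        CtTriplicate(record.embryo_id, Assay.MT, tuple(mt_vals), ct_cap=cap),
        CtTriplicate(record.embryo_id, Assay.ALU, tuple(alu_vals), ct_cap=cap),
    )


# --- bin counts --------------------------------------------------------------

def build_synthetic_grid(
    chromosomes: Sequence[str] | None = None,
    n_bins_per_chrom: int = 120,
    bin_width: int = 100_000,
    gc_range: tuple[float, float] = (0.30, 0.60),
    seed: int = 0,
) -> BinGrid:
    """A fixed-width synthetic bin grid with random GC fractions.

    Real grids have variable width and fixed unique-mappability content;
    the synthetic grid records the canonical 100 mappable 36-mers per bin
    and unit reference weights.
    """
    chromosomes = list(chromosomes) if chromosomes is not None else list(AUTOSOMES)
    rng = _rng(seed, _S_GRID)
    rows = []
    for chrom in chromosomes:
        for j in range(n_bins_per_chrom):
            rows.append(
                {
                    "chrom": chrom,
                    "start": j * bin_width,
                    "end": (j + 1) * bin_width,
                    "gc_fraction": float(rng.uniform(*gc_range)),
                    "mappable_36mers": 100,
                    "reference_weight": 1.0,
                }
            )
    return BinGrid(pd.DataFrame(rows, columns=GRID_COLUMNS))


def gc_bias_curve(gc: np.ndarray, coefficients: tuple[float, float, float]) -> np.ndarray:
    """Quadratic amplification-bias curve evaluated at GC fractions."""
    c0, c1, c2 = coefficients
    return np.maximum(c0 + c1 * gc + c2 * gc * gc, 0.05)


def simulate_bin_counts(
    record: EmbryoRecord, grid: BinGrid, config: SimulationConfig
) -> BinCountVector:
    """Negative-binomial per-bin read counts with GC bias and planted
    whole-chromosome gains/losses.

    The per-bin expectation is mean_reads_per_bin * (copies/2) *
    gc_bias(gc) * reference_weight; counts are drawn negative-binomially
    with dispersion ``nb_dispersion`` (variance mu + d*mu^2), or Poisson
    when the dispersion is zero.
    """
    rng = _rng(config.seed, _S_BINS, record.embryo_id)
    copy_state = {c: s for c, s in record.aneuploid_chromosomes}
    chroms = grid.bins["chrom"].to_numpy()
    copies = np.array([copy_state.get(c, 2) for c in chroms], dtype=float)
    gc = grid.bins["gc_fraction"].to_numpy(dtype=float)
    weight = grid.bins["reference_weight"].to_numpy(dtype=float)
    mu = (
        config.mean_reads_per_bin
        * (copies / 2.0)
        * gc_bias_curve(gc, config.gc_bias_coefficients)
        * weight
    )
    d = config.nb_dispersion
    if d <= 1e-12:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / d
        p = 1.0 / (1.0 + d * mu)
        counts = rng.negative_binomial(n, p)
    return BinCountVector(embryo_id=record.embryo_id, raw_count=counts.astype(np.int64))


# --- mito pileup -------------------------------------------------------------

def simulate_mito_pileup(
    record: EmbryoRecord,
    config: SimulationConfig,
    n_sites: int = MT_GENOME_LENGTH,
    depth_mean: float = 150.0,
    planted_heteroplasmies: Sequence[tuple[int, float]] = (),
) -> MitoPileup:
    """Position-resolved mitochondrial pileup with planted heteroplasmies.

    Depth is Poisson(depth_mean) per site; alternate counts are binomial
    with the planted fraction at listed sites and with the sequencing error
    rate elsewhere.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    planted = dict()
    for site, fraction in planted_heteroplasmies:
        if not 1 <= site <= n_sites:
            raise ValueError(f"planted site {site} outside 1..{n_sites}")
        if not 0.0 < fraction < 1.0:
            raise ValueError(f"planted fraction must lie in (0, 1), got {fraction}")
        planted[int(site)] = float(fraction)
    rng = _rng(config.seed, _S_PILEUP, record.embryo_id)
    positions = np.arange(1, n_sites + 1)
    depth = rng.poisson(depth_mean, size=n_sites)
    frac = np.full(n_sites, config.error_rate)
    for site, fraction in planted.items():
        frac[site - 1] = fraction
    alt = rng.binomial(depth, frac)
    ref = depth - alt
    return MitoPileup(
        embryo_id=record.embryo_id, positions=positions, ref_count=ref, alt_count=alt
    )


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``config`` with every effect parameter at its null value.

    Age effects and the aneuploidy effect become 1 and the elevated
    non-implanter fraction 0, so all groups share one latent distribution.
    """
    base = config or SimulationConfig()
    return replace(
        base,
        blastocyst_age_effect=1.0,
        cleavage_age_effect=1.0,
        aneuploidy_effect=1.0,
        nonimplanter_elevated_fraction=0.0,
        **overrides,
    )
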