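"""Bundled reference data.

``TE_REFERENCE``: 23 euploid trophectoderm biopsies with paired mtDNA
measurements — the qPCR relative quantity (2^-ddCt against an Alu-normalised
reference sample) and the sequencing measure (percent of aligned bases on the
mitochondrial genome) — plus the clinical outcome after single-embryo
transfer (outcome is unknown for two samples). The paired viability cutoffs
for this dataset are 0.003 (qPCR) and 0.07% (NGS).

``BLASTOCYST_COHORT_COMPOSITION``: per-maternal-age euploid/aneuploid counts
of a 302-blastocyst screening cohort; the synthetic generator uses it as the
default age distribution and per-age aneuploidy rate.
"""

from __future__ import annotations

import pandas as pd

# (sample id, qPCR relative quantity, NGS mito percent, outcome)
_TE_ROWS = [
    ("A1", 0.0004047, 0.05, "implanted"),
    ("A2", 0.000131, 0.03, "implanted"),
    ("A3", 0.001257, 0.05, "implanted"),
    ("A4", 0.00103, 0.04, "not_implanted"),
    ("A5", 0.00026, 0.03, "implanted"),
    ("A6", 0.000406, 0.03, "implanted"),
    ("A7", 0.000669, 0.03, "not_implanted"),
    ("A8", 0.00151, 0.04, "implanted"),
    ("A9", 0.00217, 0.05, "implanted"),
    ("A10", 0.001208, 0.06, "not_implanted"),
    ("A11", 0.000548, 0.04, "not_implanted"),
    ("A12", 0.001932, 0.04, "unknown"),
    ("B1", 0.00341, 0.08, "not_implanted"),
    ("B2", 0.0164158, 0.32, "not_implanted"),
    ("B3", 0.00643, 0.20, "not_implanted"),
    ("B4", 0.000602, 0.04, "unknown"),
    ("B5", 0.01075, 0.11, "not_implanted"),
    ("B6", 0.00222, 0.06, "not_implanted"),
    ("B7", 0.0033, 0.11, "not_implanted"),
    ("B8", 0.00426, 0.13, "not_implanted"),
    ("B9", 0.00412, 0.16, "not_implanted"),
    ("B10", 0.0060, 0.09, "not_implanted"),
    ("B11", 0.0069, 0.08, "not_implanted"),
]

QPCR_CUTOFF = 0.003
NGS_CUTOFF_PERCENT = 0.07


def te_reference() -> pd.DataFrame:
    """The bundled 23-sample trophectoderm dataset as a DataFrame.

    Columns: ``embryo_id``, ``qpcr_rq``, ``ngs_percent``, ``outcome``
    (``implanted`` / ``not_implanted`` / ``unknown``).
    """
    return pd.DataFrame(
        _TE_ROWS, columns=["embryo_id", "qpcr_rq", "ngs_percent", "outcome"]
    )


# age -> (n euploid, n aneuploid) blastocysts
BLASTOCYST_COHORT_COMPOSITION: dict[int, tuple[int, int]] = {
    26: (1, 0),
    29: (1, 0),
    30: (9, 5),
    31: (9, 3),
    32: (7, 3),
    33: (9, 3),
    34: (8, 1),
    35: (10, 2),
    36: (26, 9),
    37: (29, 12),
    38: (28, 6),
    39: (18, 18),
    40: (19, 7),
    41: (16, 15),
    42: (13, 15),
}


def default_age_weights() -> dict[int, float]:
    """Per-age sampling weights proportional to the reference cohort."""
    total = sum(e + a for e, a in BLASTOCYST_COHORT_COMPOSITION.values())
    return {
        age: (e + a) / total for age, (e, a) in BLASTOCYST_COHORT_COMPOSITION.items()
    }


def default_aneuploidy_rate_by_age() -> dict[int, float]:
    """Per-age aneuploidy probability from the reference cohort counts.

    Ages with a single embryo observed carry no usable rate estimate; they
    fall back to the cohort-wide rate.
    """
    total_e = sum(e for e, _ in BLASTOCYST_COHORT_COMPOSITION.values())
    total_a = sum(a for _, a in BLASTOCYST_COHORT_COMPOSITION.values())
    overall = total_a / (total_e + total_a)
    rates = {}
    for age, (e, a) in BLASTOCYST_COHORT_COMPOSITION.items():
        n = e + a
        rates[age] = a / n if n >= 5 else overall
    return rates
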