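"""Somatic-variant retention filters and substitution-spectrum analysis.

Retention rules (boundaries read literally from their source phrasing):
coverage "lower than 25" removed, hence retained at exactly 25; variant
allele frequency "lower than 5%" removed, retained at exactly 0.05;
population minor allele frequency "> 1%" removed as a polymorphism, so a
variant at exactly 0.01 (or with no population record) is retained.

The spectrum is tallied over the 12 ordered ref>alt classes without
pyrimidine-strand collapsing — C>T and G>A are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SUBSTITUTION_CLASSES
from .errors import ValidationError

REQUIRED_COLUMNS = (
    "sample_id", "chromosome", "position", "ref_base", "alt_base",
    "coverage", "vaf", "population_maf",
)


def validate_variants(records: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and record invariants; returns the table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"variant table lacks column(s): {missing}")
    if len(records):
        if (records["ref_base"] == records["alt_base"]).any():
            raise ValidationError("ref_base must differ from alt_base")
        bad_vaf = ~records["vaf"].between(0.0, 1.0)
        if bad_vaf.any():
            raise ValidationError(
                f"vaf outside [0, 1] in {int(bad_vaf.sum())} record(s)"
            )
        if (records["coverage"] < 0).any():
            raise ValidationError("coverage must be >= 0")
    return records


def filter_variants(
    records: pd.DataFrame,
    min_coverage: int = 25,
    min_vaf: float = 0.05,
    max_maf: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the retention filters; return survivors and per-rule counts.

    A record is retained iff coverage >= min_coverage, vaf >= min_vaf and
    its population MAF is missing or <= max_maf. The removal report counts
    each rule independently (a record can fail several).
    """
    validate_variants(records)
    if records.empty:
        return records.copy(), {"fail_coverage": 0, "fail_vaf": 0, "fail_maf": 0}
    fail_cov = records["coverage"] < min_coverage
    fail_vaf = records["vaf"] < min_vaf
    maf = records["population_maf"]
    fail_maf = maf.notna() & (maf > max_maf)
    keep = ~(fail_cov | fail_vaf | fail_maf)
    report = {
        "fail_coverage": int(fail_cov.sum()),
        "fail_vaf": int(fail_vaf.sum()),
        "fail_maf": int(fail_maf.sum()),
    }
    return records[keep].copy(), report


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts and percentages over the 12 ordered substitution classes.

    ``percentages`` is None when the spectrum is empty (undefined, not 0).
    """

    counts: dict[str, int]
    percentages: dict[str, float] | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def substitution_spectrum(records: pd.DataFrame) -> SubstitutionSpectrum:
    """Tally the 12-class substitution spectrum of an SNV table."""
    validate_variants(records)
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    if len(records):
        classes = records["ref_base"].str.upper() + ">" + records["alt_base"].str.upper()
        bad = ~classes.isin(SUBSTITUTION_CLASSES)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} record(s) are not single-nucleotide "
                f"substitutions over ACGT"
            )
        for cls, n in classes.value_counts().items():
            counts[cls] = int(n)
    total = sum(counts.values())
    if total == 0:
        return SubstitutionSpectrum(counts=counts, percentages=None)
    percentages = {c: 100.0 * n / total for c, n in counts.items()}
    return SubstitutionSpectrum(counts=counts, percentages=percentages)


def per_sample_counts(records: pd.DataFrame) -> pd.Series:
    """Number of variants per sample (empty table -> empty series)."""
    if records.empty:
        return pd.Series(dtype=int, name="n_variants")
    return (
        records.groupby("sample_id").size().rename("n_variants").astype(int)
    )
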