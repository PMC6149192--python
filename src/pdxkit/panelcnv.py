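"""Amplicon-panel copy-number preprocessing and gene-level estimation.

Targeted cancer panels amplify exons in primer pools; pool composition and
poorly performing amplicons bias coverage. Preprocessing removes amplicons
whose mean control-sample count falls in the lowest 5th percentile of
detectable amplicons and amplicons with a coefficient of variation >= 0.3
across the control samples, then rescales each pool so pool medians agree
within a sample. Gene copy number is 2 x the median tumor/normal count
ratio over a gene's surviving amplicons (a robust, gene-level substitute
for full segmentation).

Amplicon tables are DataFrames indexed by amplicon_id with columns
``gene_id``, ``pool`` and one numeric column per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .wescnv import CopyNumberProfile

log = logging.getLogger(__name__)

META_COLS = ("gene_id", "pool")


def _sample_cols(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c not in META_COLS]


def _check_records(records: pd.DataFrame) -> None:
    for col in META_COLS:
        if col not in records.columns:
            raise ValidationError(f"amplicon table lacks required column {col!r}")
    counts = records[_sample_cols(records)]
    if (counts.to_numpy() < 0).any():
        raise ValidationError("amplicon counts must be >= 0")


def filter_amplicons(
    records: pd.DataFrame,
    control_cols: list[str],
    percentile: float = 5.0,
    cv_threshold: float = 0.3,
    mean_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Remove low-count and high-variability amplicons.

    Removal rules, evaluated on the control samples:

    * undetectable: mean count 0;
    * low count: mean count <= the ``percentile``-th percentile (linear
      interpolation) of detectable amplicons' means — ties at the
      threshold are removed;
    * high CV: sd/mean >= ``cv_threshold``, with the sample (n-1) standard
      deviation across control samples.

    The percentile threshold is established once from the full detectable
    panel; pass the returned value back as ``mean_threshold`` to re-apply
    the same filter (which makes the operation idempotent).

    Returns ``(retained, removal_report, mean_threshold)``; the report has
    columns amplicon_id, reason, value.
    """
    _check_records(records)
    missing = [c for c in control_cols if c not in records.columns]
    if missing:
        raise ValidationError(f"control sample column(s) not found: {missing}")
    counts = records[list(control_cols)].astype(float)
    means = counts.mean(axis=1)
    detectable = means > 0
    if not detectable.any():
        raise AnalysisError("no detectable (nonzero-count) amplicon in panel")
    if mean_threshold is None:
        mean_threshold = float(np.percentile(means[detectable], percentile))

    with np.errstate(invalid="ignore", divide="ignore"):
        cv = counts.std(axis=1, ddof=1) / means
    cv = cv.fillna(0.0)  # single control sample: no variability evidence

    report_rows = []
    for amp in records.index:
        if not detectable.loc[amp]:
            report_rows.append((amp, "undetectable", 0.0))
        elif means.loc[amp] <= mean_threshold:
            report_rows.append((amp, "low_count", float(means.loc[amp])))
        elif cv.loc[amp] >= cv_threshold:
            report_rows.append((amp, "high_cv", float(cv.loc[amp])))
    report = pd.DataFrame(
        report_rows, columns=["amplicon_id", "reason", "value"]
    ).set_index("amplicon_id")
    retained = records.drop(index=report.index)
    if retained.empty:
        raise AnalysisError("all amplicons removed by filtering")
    log.info(
        "amplicon filter: retained %d / %d (removed: %s)",
        len(retained), len(records), report["reason"].value_counts().to_dict(),
    )
    return retained, report, mean_threshold


def pool_normalize(
    records: pd.DataFrame,
    sample_cols: list[str] | None = None,
    target: str = "global_median",
) -> pd.DataFrame:
    """Rescale each pool's counts so pool medians agree within a sample.

    For every sample, pool *p*'s counts are multiplied by
    ``target_value / median_p``. ``target="global_median"`` (default) uses
    the sample's median count over all amplicons, preserving the library
    scale; ``target="unit"`` sets every pool median to 1 (pure relative
    values). Relative values within a pool are preserved either way.
    """
    _check_records(records)
    if sample_cols is None:
        sample_cols = _sample_cols(records)
    if target not in ("global_median", "unit"):
        raise ValidationError(f"unknown pool-normalization target {target!r}")
    out = records.copy()
    out[sample_cols] = out[sample_cols].astype(float)
    for col in sample_cols:
        values = records[col].astype(float)
        goal = float(values.median()) if target == "global_median" else 1.0
        for pool, idx in records.groupby("pool").groups.items():
            med = float(values.loc[idx].median())
            if med <= 0:
                raise AnalysisError(
                    f"pool {pool} has non-positive median in sample {col}"
                )
            out.loc[idx, col] = values.loc[idx] * (goal / med)
    return out


def gene_copy_number(
    records: pd.DataFrame,
    tumor_col: str,
    control_cols: list[str],
    sample_id: str = "tumor",
    library_normalize: bool = True,
) -> CopyNumberProfile:
    """Gene-level copy number: 2 x median amplicon tumor/normal ratio.

    Per amplicon, the ratio is tumor count over the mean control count;
    per gene, cn = 2 x median of its amplicons' ratios. With
    ``library_normalize`` (default) each sample column is first divided by
    its median over the shared amplicons, so a global scaling of the tumor
    library cancels (assumes the median amplicon is copy-neutral). Genes
    whose amplicons all have zero control mean are omitted and logged.
    """
    _check_records(records)
    if tumor_col not in records.columns:
        raise ValidationError(f"tumor column {tumor_col!r} not found")
    missing = [c for c in control_cols if c not in records.columns]
    if missing:
        raise ValidationError(f"control sample column(s) not found: {missing}")
    if records.empty:
        raise AnalysisError("no shared amplicons between tumor and controls")

    tumor = records[tumor_col].astype(float)
    controls = records[list(control_cols)].astype(float)
    if library_normalize:
        t_med = float(tumor.median())
        if t_med <= 0:
            raise AnalysisError("tumor library median is zero")
        tumor = tumor / t_med
        controls = controls / controls.median(axis=0)
    normal_mean = controls.mean(axis=1)

    usable = normal_mean > 0
    dropped_amps = int((~usable).sum())
    if dropped_amps:
        log.warning("omitting %d amplicon(s) with zero control mean", dropped_amps)
    ratio = tumor[usable] / normal_mean[usable]
    genes = records.loc[usable, "gene_id"]
    cn = 2.0 * ratio.groupby(genes).median()
    skipped = sorted(set(records["gene_id"]) - set(cn.index))
    if skipped:
        log.warning("genes with no surviving amplicons omitted: %s", skipped)
    baseline = pd.Series(2.0, index=cn.index, name="baseline")
    return CopyNumberProfile(sample_id=sample_id, cn=cn.rename("cn"), baseline=baseline)
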