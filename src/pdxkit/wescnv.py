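"""Read-density copy-number estimation from exome read counts.

The model: a gene's read density is its (uniquely mapped) read count
divided by its total exon length. The average density of a panel of
normal-karyotype WBC samples defines the diploid reference; a tumor
gene's copy number is the density ratio scaled by the baseline ploidy
(2 for autosomes, 1 for the sex chromosomes of male samples). The ratio
is median-centred over autosomal genes so that a global scaling of the
tumor library cancels — this assumes the median autosomal gene is
copy-neutral, the standard assumption of read-depth CNV tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError, ValidationError

log = logging.getLogger(__name__)

_SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


def _merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if a >= b:
            raise ValidationError(f"invalid exon interval ({a}, {b}): start >= end")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene: id, chromosome, merged 0-based half-open exon intervals."""

    gene_id: str
    chromosome: str
    exon_intervals: tuple[tuple[int, int], ...]
    exon_length: int = field(init=False)
    is_sex_chromosome: bool = field(init=False)

    def __post_init__(self):
        merged = _merge_intervals(self.exon_intervals)
        object.__setattr__(self, "exon_intervals", merged)
        object.__setattr__(self, "exon_length", sum(b - a for a, b in merged))
        object.__setattr__(
            self, "is_sex_chromosome", self.chromosome in _SEX_CHROMOSOMES
        )
        if self.exon_length <= 0:
            raise ValidationError(f"gene {self.gene_id} has zero exon length")

    def baseline_ploidy(self) -> float:
        """2 for autosomes, 1 for sex chromosomes (male samples)."""
        return 1.0 if self.is_sex_chromosome else 2.0


@dataclass
class CopyNumberProfile:
    """Per-gene estimated copy number for one sample."""

    sample_id: str
    cn: pd.Series  # gene_id -> estimated copy number (non-negative real)
    baseline: pd.Series  # gene_id -> 2 (autosomal) or 1 (sex, male)

    def __post_init__(self):
        self.cn = self.cn.astype(float)
        self.baseline = self.baseline.astype(float).reindex(self.cn.index)
        if self.baseline.isna().any():
            missing = list(self.baseline.index[self.baseline.isna()])
            raise ValidationError(f"genes without baseline ploidy: {missing}")
        if (self.cn < 0).any():
            raise ValidationError("copy numbers must be >= 0")
        if not self.baseline.isin([1.0, 2.0]).all():
            raise ValidationError("baseline ploidy must be 1 or 2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cn": self.cn, "baseline": self.baseline})


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson concordance of two log2-scale copy-number profiles."""

    sample_a: str
    sample_b: str
    n_genes: int
    pearson_r: float
    pseudocount: float


def read_density(counts: pd.Series, gene_models: list[GeneModel]) -> pd.Series:
    """Per-gene read density: count / exon_length."""
    by_id = {m.gene_id: m for m in gene_models}
    missing = [g for g in counts.index if g not in by_id]
    if missing:
        raise ValidationError(f"no gene model for: {missing}")
    if (counts < 0).any():
        raise ValidationError("read counts must be >= 0")
    lengths = pd.Series({g: by_id[g].exon_length for g in counts.index})
    return (counts / lengths).rename(counts.name)


def panel_baseline(normal_densities: pd.DataFrame | list[pd.Series]) -> pd.Series:
    """Mean per-gene density of the normal WBC panel (the diploid standard).

    Genes with zero mean density are returned as 0 and flagged by the
    caller as unusable.
    """
    if isinstance(normal_densities, list):
        if not normal_densities:
            raise ValidationError("empty normal panel")
        normal_densities = pd.concat(normal_densities, axis=1)
    if normal_densities.shape[1] < 1:
        raise ValidationError("empty normal panel")
    if normal_densities.isna().any().any():
        raise ValidationError("normal samples must share the same gene universe")
    return normal_densities.mean(axis=1)


def to_copy_number(
    tumor_density: pd.Series,
    baseline_density: pd.Series,
    gene_models: list[GeneModel],
    sex: str = "male",
    sample_id: str = "tumor",
    library_normalize: bool = True,
) -> CopyNumberProfile:
    """Per-gene copy number from the tumor/baseline density ratio.

    ``cn(g) = ploidy(g) * tumor_density(g) / baseline_density(g)``, with
    ploidy 2 for autosomes and 1 for sex chromosomes. With
    ``library_normalize`` (default) the ratio is first divided by its
    median over autosomal genes, so the estimate is invariant to a global
    scaling of the tumor library. Genes with unusable (zero) baseline are
    omitted and logged.
    """
    if sex != "male":
        raise ConfigurationError(
            f"only male samples are supported (baseline 2 autosomal / 1 sex); "
            f"got sex={sex!r}"
        )
    by_id = {m.gene_id: m for m in gene_models}
    missing = [g for g in tumor_density.index if g not in by_id]
    if missing:
        raise ValidationError(f"no gene model for: {missing}")
    shared = tumor_density.index.intersection(baseline_density.index)
    usable = shared[baseline_density.loc[shared] > 0]
    dropped = sorted(set(shared) - set(usable))
    if dropped:
        log.warning("omitting %d gene(s) with zero baseline density: %s",
                    len(dropped), dropped[:10])
    ratio = tumor_density.loc[usable] / baseline_density.loc[usable]
    ploidy = pd.Series({g: by_id[g].baseline_ploidy() for g in usable})
    if library_normalize:
        auto = ratio[ploidy == 2.0]
        scale = float(np.median(auto)) if len(auto) else float(np.median(ratio))
        if scale <= 0:
            raise AnalysisError("median density ratio is zero; cannot normalize")
        ratio = ratio / scale
    cn = (ploidy * ratio).rename("cn")
    return CopyNumberProfile(sample_id=sample_id, cn=cn, baseline=ploidy.rename("baseline"))


def call_gain_loss(
    profile: CopyNumberProfile,
    gain_threshold: float = 3.0,
    loss_threshold: float = 1.0,
) -> pd.Series:
    """Per-gene {gain, neutral, loss} calls.

    Thresholds are stated on the autosomal (diploid) scale and rescaled by
    ``baseline/2`` for sex chromosomes; both boundaries are closed (a copy
    number exactly at a threshold is called gain/loss).
    """
    if loss_threshold >= gain_threshold:
        raise ConfigurationError(
            f"loss_threshold ({loss_threshold}) must be < gain_threshold "
            f"({gain_threshold})"
        )
    scale = profile.baseline / 2.0
    calls = pd.Series("neutral", index=profile.cn.index, name="call")
    calls[profile.cn >= gain_threshold * scale] = "gain"
    calls[profile.cn <= loss_threshold * scale] = "loss"
    return calls


def cn_correlation(
    profile_a: CopyNumberProfile,
    profile_b: CopyNumberProfile,
    pseudocount: float = 0.01,
) -> ConcordanceResult:
    """Pearson r of log2(cn + pseudocount) over the shared gene set.

    The pseudocount keeps homozygous deletions (cn = 0) finite on the log
    scale.
    """
    shared = profile_a.cn.index.intersection(profile_b.cn.index)
    if len(shared) < 3:
        raise AnalysisError(
            f"need >= 3 shared genes for concordance, got {len(shared)}"
        )
    a = np.log2(profile_a.cn.loc[shared].to_numpy() + pseudocount)
    b = np.log2(profile_b.cn.loc[shared].to_numpy() + pseudocount)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AnalysisError("zero variance in a profile; correlation undefined")
    r = stats.pearsonr(a, b).statistic
    return ConcordanceResult(
        sample_a=profile_a.sample_id,
        sample_b=profile_b.sample_id,
        n_genes=len(shared),
        pearson_r=float(r),
        pseudocount=pseudocount,
    )
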