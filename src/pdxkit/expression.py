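"""RPKM quantification and fold-change / significance DEG calling.

RPKM(g, s) = count(g, s) * 1e9 / (library_size(s) * length(g)): reads per
kilobase of transcript per million mapped reads. Genes are quantifiable
when their total count across the samples of a comparison reaches a
minimum (default 10 reads). A gene is differentially expressed when its
fold change is at least 2 (either direction) and its p-value is below
0.05. The count test is self-contained: an exact conditional binomial
test on pooled counts for 1-vs-1 designs, a two-sample t-test on
log2(normalized count + 1) for replicated designs; no multiple-testing
correction by default (a Benjamini-Hochberg option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ValidationError


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``counts`` is gene x sample; ``gene_lengths`` in bases. Library sizes
    are the column sums. Zero counts map to 0; a zero library size is an
    error.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValidationError(f"no length for gene(s): {list(missing[:10])}")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise AnalysisError(f"zero library size in sample(s): {bad}")
    return counts.astype(float).mul(1e9).div(lib, axis=1).div(lengths, axis=0)


def quantifiable_genes(counts: pd.DataFrame, min_reads: int = 10) -> pd.Index:
    """Genes whose total count across all given samples is >= min_reads."""
    if counts.empty:
        return counts.index[:0]
    return counts.index[counts.sum(axis=1) >= min_reads]


@dataclass(frozen=True)
class DegResult:
    gene_id: str
    fold_change: float  # treated / control, on normalized means
    p_value: float
    is_de: bool


def _normalized(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to the mean library size (depth normalization)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise AnalysisError("zero library size")
    return counts.astype(float).div(lib, axis=1) * float(lib.mean())


def call_deg(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_reads: int = 10,
    pseudocount: float = 1.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Differential expression between two conditions.

    Both inputs are gene x sample count matrices over the same genes.
    Fold change is the ratio of pseudocounted, depth-normalized condition
    means, so swapping conditions maps fc -> 1/fc. The p-value comes from
    a binomial exact test on pooled counts (1 sample per condition) or a
    two-sample t-test on log2(normalized + 1) (replicated). ``is_de``
    requires fc >= fc_threshold or <= 1/fc_threshold *and* p < alpha
    (BH-adjusted when ``fdr``). Returns a DataFrame indexed by gene with
    columns fold_change, p_value, is_de.
    """
    shared = treated.index.intersection(control.index)
    if len(shared) == 0:
        raise AnalysisError("no overlapping genes between conditions")
    treated = treated.loc[shared]
    control = control.loc[shared]
    quant = quantifiable_genes(pd.concat([treated, control], axis=1), min_reads)
    t = treated.loc[quant]
    c = control.loc[quant]
    lib_t = float(treated.sum().sum())
    lib_c = float(control.sum().sum())

    tn = _normalized(pd.concat([treated, control], axis=1))
    t_norm = tn.loc[quant, treated.columns]
    c_norm = tn.loc[quant, control.columns]
    fc = (t_norm.mean(axis=1) + pseudocount) / (c_norm.mean(axis=1) + pseudocount)

    if treated.shape[1] == 1 and control.shape[1] == 1:
        p0 = lib_t / (lib_t + lib_c)
        pvals = pd.Series(
            [
                stats.binomtest(int(kt), int(kt + kc), p0).pvalue if kt + kc > 0 else 1.0
                for kt, kc in zip(t.iloc[:, 0], c.iloc[:, 0])
            ],
            index=quant,
        )
    else:
        lt = np.log2(t_norm.to_numpy() + 1.0)
        lc = np.log2(c_norm.to_numpy() + 1.0)
        res = stats.ttest_ind(lt, lc, axis=1)
        pvals = pd.Series(np.nan_to_num(res.pvalue, nan=1.0), index=quant)

    padj = pvals
    if fdr:
        padj = pd.Series(
            stats.false_discovery_control(pvals.to_numpy(), method="bh"), index=quant
        )
    is_de = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (padj < alpha)
    return pd.DataFrame(
        {"fold_change": fc, "p_value": pvals, "is_de": is_de}
    ).rename_axis("gene_id")


def deg_summary(results: pd.DataFrame) -> dict:
    """DE count with up/down split."""
    de = results[results["is_de"]]
    return {
        "n_de": int(len(de)),
        "n_up": int((de["fold_change"] > 1).sum()),
        "n_down": int((de["fold_change"] < 1).sum()),
        "n_tested": int(len(results)),
    }
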