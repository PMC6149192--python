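"""Synthetic-data generators for every input the pipeline consumes.

Each generator emulates one data type of a PDX genomic study — xenograft
read sets with mouse contamination, per-gene exome coverage with planted
copy-number gains/losses over a diploid male baseline, somatic variant
tables with a known 12-class substitution spectrum, plasma cfDNA cohorts
whose CCND1/CDKN2A copy-ratio is linear in log10 EBV DNA load, qPCR Ct
values derived from true copy numbers, and two-condition RNA count
matrices with planted fold changes.

Every generator draws from a named sub-stream of the master seed
(:meth:`pdxkit.config.SimulationConfig.rng`), admits a zero-noise mode in
which the downstream estimator recovers truth exactly, and returns plain
in-memory objects (strings, pandas tables); file serialization lives in
:mod:`pdxkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QPCR_TARGETS, SUBSTITUTION_CLASSES, SimulationConfig
from .errors import ConfigurationError, ValidationError
from .wescnv import GeneModel

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# references and reads
# ---------------------------------------------------------------------------

def gen_reference_pair(config: SimulationConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Generate a human-like / mouse-like reference genome pair.

    Both genomes have two chromosomes, ``autosome`` and ``chrX``, of
    uppercase ACGT. The mouse-like genome is the human-like one with each
    base independently substituted (to a different base, uniformly) with
    probability ``config.divergence``, so the observed mismatch fraction is
    binomial around the divergence.
    """
    if config.genome_length < config.read_length:
        raise ConfigurationError(
            f"genome_length ({config.genome_length}) must be >= read_length "
            f"({config.read_length})"
        )
    rng = config.rng("reference")
    human: dict[str, str] = {}
    mouse: dict[str, str] = {}
    for chrom, length in (("autosome", config.genome_length), ("chrX", config.chrx_length)):
        if length <= 0:
            raise ConfigurationError(f"zero-length genome requested for {chrom}")
        h = rng.integers(0, 4, size=length)
        mutate = rng.random(length) < config.divergence
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=length)
        m = np.where(mutate, (h + shift) % 4, h)
        human[chrom] = "".join(_BASES[h])
        mouse[chrom] = "".join(_BASES[m])
    return human, mouse


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin: str  # hidden truth label: "human" or "mouse"


def gen_reads(
    config: SimulationConfig,
    references: tuple[dict[str, str], dict[str, str]],
) -> list[SimulatedRead]:
    """Draw labeled single-end reads from the two references.

    Each read originates from the mouse-like genome with probability
    ``config.contamination_fraction`` (hidden truth label carried on the
    record) and is sampled uniformly from a uniformly chosen chromosome,
    with per-base sequencing errors at ``config.read_error_rate``.
    """
    human, mouse = references
    rng = config.rng("reads")
    L = config.read_length
    for genome in (human, mouse):
        for chrom, seq in genome.items():
            if L > len(seq):
                raise ConfigurationError(
                    f"read_length {L} exceeds length of {chrom} ({len(seq)})"
                )
    reads: list[SimulatedRead] = []
    chroms = list(human)
    for i in range(config.n_reads):
        is_mouse = rng.random() < config.contamination_fraction
        genome = mouse if is_mouse else human
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, len(genome[chrom]) - L + 1))
        arr = np.frombuffer(genome[chrom][start : start + L].encode(), dtype="S1")
        codes = np.searchsorted(_BASES.astype("S1"), arr)
        err = rng.random(L) < config.read_error_rate
        codes = np.where(err, (codes + rng.integers(1, 4, size=L)) % 4, codes)
        reads.append(
            SimulatedRead(
                read_id=f"read{i:06d}",
                sequence="".join(_BASES[codes]),
                origin="mouse" if is_mouse else "human",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# gene models and exome coverage
# ---------------------------------------------------------------------------

def gen_gene_models(config: SimulationConfig, frac_chrx: float = 0.1) -> list[GeneModel]:
    """Deterministic synthetic gene models.

    ``n_genes`` genes named ``G0001``..; the last ``frac_chrx`` fraction sit
    on chrX (baseline ploidy 1 in males). Exon lengths cycle through a fixed
    set of realistic totals so results do not depend on a particular draw.
    """
    lengths = (800, 1200, 1500, 2000, 3000, 4500)
    models = []
    n_x = int(round(config.n_genes * frac_chrx))
    for i in range(config.n_genes):
        on_x = i >= config.n_genes - n_x
        length = lengths[i % len(lengths)]
        # single merged exon suffices for density arithmetic
        models.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}",
                chromosome="chrX" if on_x else "autosome",
                exon_intervals=((0, length),),
            )
        )
    return models


def gen_coverage(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    truth: dict[str, int] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene read counts for one tumor and ``n_normals`` WBC normals.

    The generator inverts the read-density copy-number model: the expected
    tumor count of gene *g* is ``depth * exon_length(g)/1000 * CN(g) /
    baseline(g)`` and normals are drawn at CN = baseline, both Poisson.

    Returns ``(tumor_counts, normal_counts)`` with genes as index and
    normal samples as columns ``N1..Nk``.
    """
    truth = dict(config.planted_cnv if truth is None else truth)
    by_id = {m.gene_id: m for m in gene_models}
    unknown = set(truth) - set(by_id)
    if unknown:
        raise ValidationError(
            f"planted copy number refers to unknown gene(s): {sorted(unknown)}"
        )
    rng = config.rng("coverage")
    genes = [m.gene_id for m in gene_models]
    base_mean = np.array(
        [config.depth * by_id[g].exon_length / 1000.0 for g in genes]
    )
    baseline = np.array([1.0 if by_id[g].is_sex_chromosome else 2.0 for g in genes])
    cn = np.array([float(truth.get(g, by_id[g].baseline_ploidy())) for g in genes])
    tumor_mean = base_mean * cn / baseline
    tumor = pd.Series(rng.poisson(tumor_mean), index=genes, name="tumor")
    normals = pd.DataFrame(
        {f"N{j + 1}": rng.poisson(base_mean) for j in range(config.n_normals)},
        index=genes,
    )
    return tumor, normals


# ---------------------------------------------------------------------------
# somatic variant tables
# ---------------------------------------------------------------------------

def gen_variant_table(
    config: SimulationConfig,
    n_per_sample: dict[str, int],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Somatic SNV table with substitution classes drawn from the spectrum.

    Coverage, VAF and population-MAF fields are populated so that a planted
    fraction of records independently fails each retention filter
    (coverage >= 25, VAF >= 5%, MAF <= 1%). Returns the table and a
    bookkeeping dict with the exact number of records failing each rule
    (``fail_coverage``, ``fail_vaf``, ``fail_maf``).
    """
    for s, n in n_per_sample.items():
        if n < 0:
            raise ConfigurationError(f"negative variant count for sample {s}: {n}")
    rng = config.rng("variants")
    classes = np.array(SUBSTITUTION_CLASSES)
    probs = np.array([config.spectrum[c] for c in SUBSTITUTION_CLASSES])
    rows = []
    book = {"fail_coverage": 0, "fail_vaf": 0, "fail_maf": 0}
    for sample, n in sorted(n_per_sample.items()):
        drawn = classes[rng.choice(len(classes), size=n, p=probs)]
        for cls in drawn:
            ref, alt = cls.split(">")
            fail_cov = rng.random() < config.frac_fail_coverage
            fail_vaf = rng.random() < config.frac_fail_vaf
            fail_maf = rng.random() < config.frac_fail_maf
            coverage = int(rng.integers(5, 25) if fail_cov else rng.integers(25, 400))
            vaf = float(rng.uniform(0.005, 0.05) if fail_vaf else rng.uniform(0.05, 1.0))
            if fail_maf:
                maf = float(rng.uniform(0.0101, 0.3))
            else:
                maf = float(rng.uniform(0.0, 0.01)) if rng.random() < 0.5 else np.nan
            book["fail_coverage"] += fail_cov
            book["fail_vaf"] += fail_vaf
            book["fail_maf"] += fail_maf
            rows.append(
                {
                    "sample_id": sample,
                    "chromosome": "autosome",
                    "position": int(rng.integers(1, 10_000_000)),
                    "ref_base": ref,
                    "alt_base": alt,
                    "coverage": coverage,
                    "vaf": vaf,
                    "population_maf": maf,
                    "consequence": "missense" if rng.random() < 0.9 else "splice_site",
                }
            )
    columns = [
        "sample_id", "chromosome", "position", "ref_base", "alt_base",
        "coverage", "vaf", "population_maf", "consequence",
    ]
    return pd.DataFrame(rows, columns=columns), book


def synthetic_snv_catalog(seed: int = 0) -> pd.DataFrame:
    """Deterministic synthetic stand-in for a five-tumor somatic SNV list.

    A 282-record catalog whose class counts follow the largest-remainder
    quota of the default spectrum (C>T 26.2%, G>A 20%, remainder uniform),
    split over five PDX tumors with per-tumor totals 34/48/52/99/49 —
    i.e. a synthetic reconstruction matching the printed marginal summaries
    of the real (undeposited) mutation list, for use wherever that list is
    the expected input. All records pass the retention filters.
    """
    n_total = 282
    probs = {c: (0.262 if c == "C>T" else 0.20 if c == "G>A" else 0.0538)
             for c in SUBSTITUTION_CLASSES}
    quota = {c: p * n_total for c, p in probs.items()}
    counts = {c: int(np.floor(q)) for c, q in quota.items()}
    short = n_total - sum(counts.values())
    for c in sorted(quota, key=lambda c: quota[c] - np.floor(quota[c]), reverse=True)[:short]:
        counts[c] += 1
    assert sum(counts.values()) == n_total
    sample_totals = {"PDX-ST": 34, "PDX-LN": 48, "PDX-LG": 52, "PDX-LV": 99, "PDX-Bone": 49}
    assert sum(sample_totals.values()) == n_total

    rng = np.random.default_rng(seed)
    class_list = [c for c in SUBSTITUTION_CLASSES for _ in range(counts[c])]
    rng.shuffle(class_list)
    samples = [s for s, n in sample_totals.items() for _ in range(n)]
    rows = []
    for sample, cls in zip(samples, class_list):
        ref, alt = cls.split(">")
        rows.append(
            {
                "sample_id": sample,
                "chromosome": "autosome",
                "position": int(rng.integers(1, 10_000_000)),
                "ref_base": ref,
                "alt_base": alt,
                "coverage": int(rng.integers(25, 400)),
                "vaf": float(rng.uniform(0.05, 1.0)),
                "population_maf": np.nan,
                "consequence": "missense" if rng.random() < 0.9 else "splice_site",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plasma cfDNA cohorts and qPCR
# ---------------------------------------------------------------------------

def _cdkn2a_loss_prob(config: SimulationConfig, log_load: np.ndarray) -> np.ndarray:
    """One-copy-loss probability, ramping 0 -> max between 5e3 and 1e5 copies/ml."""
    x0, x1 = np.log10(5_000.0), 5.0
    ramp = np.clip((log_load - x0) / (x1 - x0), 0.0, 1.0)
    return config.cdkn2a_loss_max_prob * ramp


def gen_plasma_cohort(
    config: SimulationConfig,
    n_patients: int = 22,
    load_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Plasma cfDNA cohort with EBV loads and gene copy numbers.

    EBV DNA loads are log-uniform on ``load_range`` (default: the
    high-load-cohort range of the configuration). The CCND1/CDKN2A ratio
    follows ``slope * log10(load) + intercept`` plus Normal noise, floored
    at a small positive minimum. CDKN2A is drawn from {2, 1, homozygous
    deletion} with one-copy-loss probability increasing in load (reaching
    ``cdkn2a_loss_max_prob`` at 1e5 copies/ml), CCND1 is set to
    ``ratio * CDKN2A`` so the per-sample ratio reproduces the linear model
    exactly, and RAD52 sits at ~2 with small noise.

    Columns: patient_id, ebv_copies_per_ml, cn_ccnd1, cn_cdkn2a, cn_rad52,
    ratio, cdkn2a_state.
    """
    lo, hi = load_range if load_range is not None else config.plasma_load_range
    if lo <= 0 or hi <= lo:
        raise ConfigurationError(
            f"load_range must be a positive increasing interval, got {(lo, hi)}"
        )
    rng = config.rng("plasma")
    x = rng.uniform(np.log10(lo), np.log10(hi), size=n_patients)
    load = 10.0 ** x
    ratio = config.plasma_slope * x + config.plasma_intercept
    ratio = ratio + rng.normal(0.0, config.plasma_noise_sd, size=n_patients)
    ratio = np.maximum(ratio, config.plasma_ratio_floor)

    u = rng.random(n_patients)
    p_loss = _cdkn2a_loss_prob(config, x)
    state = np.where(
        u < config.cdkn2a_homdel_prob,
        "homdel",
        np.where(u < config.cdkn2a_homdel_prob + p_loss, "loss", "neutral"),
    )
    base = {"homdel": config.cdkn2a_homdel_cn, "loss": 1.0, "neutral": 2.0}
    cdkn2a = np.array([base[s] for s in state])
    noise = rng.normal(0.0, config.plasma_cn_noise_sd, size=n_patients)
    cdkn2a = np.maximum(cdkn2a + np.where(state == "homdel", 0.0, noise), 0.01)
    ccnd1 = ratio * cdkn2a
    rad52 = np.maximum(
        2.0 + rng.normal(0.0, config.plasma_cn_noise_sd, size=n_patients), 0.01
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
            "ebv_copies_per_ml": load,
            "cn_ccnd1": ccnd1,
            "cn_cdkn2a": cdkn2a,
            "cn_rad52": rad52,
            "ratio": ccnd1 / cdkn2a,
            "cdkn2a_state": state,
        }
    )


def gen_qpcr(
    config: SimulationConfig,
    truth: dict[str, float],
    sample_id: str = "sample",
    control_target: str = "RAD52",
) -> pd.DataFrame:
    """qPCR Ct measurements for one sample plus a healthy-PBMC calibrator.

    Inverts the comparative-Ct quantification model: with amplification
    factor ``A = 1 + qpcr_efficiency`` (2 at perfect doubling), a target at
    copy number CN comes up ``log_A(CN/2)`` cycles earlier than in the
    diploid calibrator. At zero Ct noise and perfect efficiency, the
    downstream ddCt estimator recovers the planted copy numbers exactly.
    Copy number 0 is emitted as a non-detect (missing Ct).

    Returns a tidy table: sample_id, target, replicate, ct (NaN = non-detect).
    """
    unknown = set(truth) - set(QPCR_TARGETS)
    if unknown:
        raise ConfigurationError(f"unknown qPCR target(s): {sorted(unknown)}")
    if control_target not in truth:
        truth = {**truth, control_target: 2.0}
    if any(cn < 0 for cn in truth.values()):
        raise ConfigurationError("copy numbers must be >= 0")
    rng = config.rng("qpcr")
    amp = 1.0 + config.qpcr_efficiency
    rows = []
    for sid, cns in ((sample_id, truth), ("calibrator", {t: 2.0 for t in truth})):
        for target, cn in sorted(cns.items()):
            for rep in range(1, config.qpcr_replicates + 1):
                if cn == 0:
                    ct = np.nan  # non-detect
                else:
                    ct = config.qpcr_base_ct[target] - np.log(cn / 2.0) / np.log(amp)
                    if config.qpcr_ct_noise_sd > 0:
                        ct += rng.normal(0.0, config.qpcr_ct_noise_sd)
                rows.append(
                    {"sample_id": sid, "target": target, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def gen_expression(
    config: SimulationConfig,
    n_de: int = 50,
    fold_change: float = 4.0,
    n_replicates: int = 3,
    base_mean: float = 100.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-condition count matrix with ``n_de`` planted up-regulated genes.

    Per-gene base means are log-normal around ``base_mean``; counts are
    Poisson. The first ``n_de`` genes (after a seeded shuffle) have treated
    mean = ``fold_change`` x control mean; all others have equal means.
    Returns ``(counts, is_de)`` where columns are ``T1..Tk, C1..Ck`` and
    ``is_de`` is the boolean truth label per gene.
    """
    if fold_change <= 0:
        raise ConfigurationError(f"fold_change must be > 0, got {fold_change}")
    if n_de > config.n_genes:
        raise ConfigurationError(
            f"n_de ({n_de}) exceeds n_genes ({config.n_genes})"
        )
    rng = config.rng("expression")
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    mu = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    de_idx = rng.permutation(config.n_genes)[:n_de]
    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True
    treated_mu = np.where(is_de & (fold_change != 1.0), mu * fold_change, mu)
    data = {}
    for j in range(n_replicates):
        data[f"T{j + 1}"] = rng.poisson(treated_mu)
    for j in range(n_replicates):
        data[f"C{j + 1}"] = rng.poisson(mu)
    counts = pd.DataFrame(data, index=genes)
    return counts, pd.Series(is_de & (fold_change != 1.0), index=genes, name="is_de")
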