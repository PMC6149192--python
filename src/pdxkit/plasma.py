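"""Plasma cfDNA copy-number biomarker.

Quantifies gene copy number from qPCR cycle thresholds by the comparative
(ddCt) method against a healthy-PBMC calibrator, forms the CCND1/CDKN2A
copy-ratio, relates it to plasma EBV DNA load by ordinary least squares on
log10 load, and classifies patients as CDK4/6-inhibitor candidates when
the ratio exceeds a cutoff (default 4, the ratio the fitted line predicts
at ~5000 EBV copies/ml).

The quantification model assumes perfect per-cycle doubling by default
(CN = 2 * 2^(-ddCt)); a lower amplification efficiency can be supplied,
replacing the base 2 by (1 + efficiency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError, ValidationError

log = logging.getLogger(__name__)

#: replicate Cts further apart than this (cycles) are flagged discordant
REPLICATE_TOLERANCE = 0.5


@dataclass(frozen=True)
class CopyNumberCall:
    """qPCR-derived copy number for one target in one sample."""

    sample_id: str
    target: str
    copy_number: float
    non_detect: bool = False
    discordant_replicates: bool = False


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of the CCND1/CDKN2A ratio on log10 EBV load."""

    slope: float
    intercept: float
    pearson_r: float
    n: int


@dataclass(frozen=True)
class BiomarkerCall:
    patient_id: str
    ratio: float
    cutoff: float
    candidate: bool


def _mean_ct(measurements: pd.DataFrame, sample_id: str, target: str):
    """(mean Ct or None if non-detect, discordant flag)."""
    sel = measurements[
        (measurements["sample_id"] == sample_id)
        & (measurements["target"] == target)
    ]["ct"]
    if sel.empty:
        return None, False
    detected = sel.dropna()
    if detected.empty:
        return None, False  # non-detect
    discordant = float(detected.max() - detected.min()) > REPLICATE_TOLERANCE
    if discordant:
        log.warning(
            "discordant replicates for %s/%s (spread %.2f cycles)",
            sample_id, target, detected.max() - detected.min(),
        )
    return float(detected.mean()), discordant


def qpcr_copy_number(
    measurements: pd.DataFrame,
    sample_id: str,
    calibrator_id: str = "calibrator",
    control_target: str = "RAD52",
    efficiency: float = 1.0,
) -> dict[str, CopyNumberCall]:
    """ddCt copy numbers for every target measured in one sample.

    Replicate Cts are averaged first; dCt = Ct(target) - Ct(control);
    ddCt = dCt(sample) - dCt(calibrator); CN = 2 * A^(-ddCt) with
    amplification factor A = 1 + efficiency (2 at perfect doubling). A
    non-detected target is reported as CN 0 with a flag.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ConfigurationError(f"efficiency must lie in (0, 1], got {efficiency}")
    for col in ("sample_id", "target", "ct"):
        if col not in measurements.columns:
            raise ValidationError(f"qPCR table lacks column {col!r}")
    amp = 1.0 + efficiency

    ctrl_s, _ = _mean_ct(measurements, sample_id, control_target)
    if ctrl_s is None:
        raise AnalysisError(
            f"control target {control_target} missing or non-detect in {sample_id}"
        )
    ctrl_c, _ = _mean_ct(measurements, calibrator_id, control_target)
    if ctrl_c is None:
        raise AnalysisError(
            f"control target {control_target} missing or non-detect in calibrator"
        )

    targets = sorted(
        set(measurements.loc[measurements["sample_id"] == sample_id, "target"])
    )
    calls: dict[str, CopyNumberCall] = {}
    for target in targets:
        ct_s, disc_s = _mean_ct(measurements, sample_id, target)
        if ct_s is None:
            calls[target] = CopyNumberCall(sample_id, target, 0.0, non_detect=True)
            continue
        ct_c, disc_c = _mean_ct(measurements, calibrator_id, target)
        if ct_c is None:
            raise AnalysisError(f"target {target} non-detect in calibrator")
        ddct = (ct_s - ctrl_s) - (ct_c - ctrl_c)
        cn = 2.0 * amp ** (-ddct)
        calls[target] = CopyNumberCall(
            sample_id, target, float(cn), discordant_replicates=disc_s or disc_c
        )
    return calls


def cnv_ratio(
    cn_ccnd1: float, cn_cdkn2a: float, epsilon: float = 0.05
) -> tuple[float, bool]:
    """CCND1/CDKN2A copy-ratio with a floored denominator.

    Returns ``(ratio, floored)``; ``floored`` is True when the CDKN2A copy
    number fell below ``epsilon`` (e.g. homozygous deletion) and the floor
    was substituted to keep the ratio finite.
    """
    if cn_ccnd1 < 0 or cn_cdkn2a < 0:
        raise ValidationError("copy numbers must be >= 0")
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be > 0")
    floored = cn_cdkn2a < epsilon
    return cn_ccnd1 / max(cn_cdkn2a, epsilon), floored


def fit_load_regression(samples: pd.DataFrame) -> RegressionFit:
    """OLS of the CCND1/CDKN2A ratio on log10 EBV load.

    ``samples`` needs columns ``ebv_copies_per_ml`` and ``ratio``.
    Zero/negative-load samples are excluded with a warning. A constant
    ratio yields slope 0 with r reported as 0 (documented convention).
    """
    for col in ("ebv_copies_per_ml", "ratio"):
        if col not in samples.columns:
            raise ValidationError(f"plasma table lacks column {col!r}")
    ok = samples["ebv_copies_per_ml"] > 0
    if (~ok).any():
        log.warning("excluding %d sample(s) with non-positive EBV load", int((~ok).sum()))
    sub = samples[ok]
    if len(sub) < 3:
        raise AnalysisError(f"need >= 3 samples with positive load, got {len(sub)}")
    x = np.log10(sub["ebv_copies_per_ml"].to_numpy(dtype=float))
    y = sub["ratio"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise AnalysisError("all EBV loads equal; slope undefined")
    if np.ptp(y) == 0:
        return RegressionFit(slope=0.0, intercept=float(y[0]), pearson_r=0.0, n=len(sub))
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(sub),
    )


def ratio_at_load(fit: RegressionFit, load: float) -> float:
    """Predicted CCND1/CDKN2A ratio at an EBV load (copies/ml)."""
    if load <= 0:
        raise ValidationError(f"load must be > 0, got {load}")
    return fit.slope * math.log10(load) + fit.intercept


def gene_load_correlation(samples: pd.DataFrame, gene: str) -> float:
    """Pearson r between a gene's copy number and log10 EBV load.

    ``gene`` names a ``cn_<gene>`` column (case-insensitive).
    """
    col = f"cn_{gene.lower()}"
    if col not in samples.columns:
        raise ValidationError(f"plasma table lacks column {col!r}")
    sub = samples[samples["ebv_copies_per_ml"] > 0]
    if len(sub) < 3:
        raise AnalysisError(f"need >= 3 samples, got {len(sub)}")
    x = np.log10(sub["ebv_copies_per_ml"].to_numpy(dtype=float))
    y = sub[col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def classify_candidate(
    patient_id: str, ratio: float, cutoff: float = 4.0
) -> BiomarkerCall:
    """CDK4/6-inhibitor candidacy: strict ratio > cutoff.

    A ratio exactly at the cutoff is *not* a candidate (strict inequality;
    the default cutoff 4 corresponds to ~5000 EBV copies/ml under the
    reference regression).
    """
    if ratio < 0:
        raise ValidationError("ratio must be >= 0")
    return BiomarkerCall(
        patient_id=patient_id, ratio=ratio, cutoff=cutoff, candidate=ratio > cutoff
    )
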