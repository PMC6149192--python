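"""Simulation and pipeline configuration.

All randomness in the synthetic-data generators flows from a single integer
seed through named sub-streams (one per output), so that each generated file
is individually reproducible and a whole run is byte-identical under the
same :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError

#: The 12 ordered single-base substitution classes (no pyrimidine-strand
#: collapsing: C>T and G>A are distinct classes, reported separately).
SUBSTITUTION_CLASSES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

#: Default substitution spectrum: the two predominant transition classes of
#: EBV-positive nasopharyngeal tumors (C>T 26.2%, G>A 20%) with the
#: remaining mass spread uniformly over the other ten classes.
DEFAULT_SPECTRUM: dict[str, float] = {
    cls: (0.262 if cls == "C>T" else 0.20 if cls == "G>A" else (1.0 - 0.462) / 10.0)
    for cls in SUBSTITUTION_CLASSES
}

#: qPCR targets used by the plasma biomarker (RAD52 is the copy-neutral
#: internal control).
QPCR_TARGETS: tuple[str, ...] = ("CCND1", "CDKN2A", "RAD52")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generators.

    The defaults emulate the study conditions of the analysis this toolkit
    implements: male patients (autosomal baseline 2, sex-chromosome
    baseline 1), a plasma CCND1/CDKN2A copy-ratio that is linear in
    log10 EBV DNA load with slope 11.11 and intercept -36.93, and a somatic
    substitution spectrum dominated by C>T (26.2%) and G>A (20%)
    transitions.

    Parameters
    ----------
    seed
        Master seed; every generator derives its own sub-stream from it.
    n_genes
        Number of genes in the synthetic gene model.
    depth
        Mean reads per kilobase of exon per sample at copy-neutral state.
    contamination_fraction
        Proportion of mouse-origin reads in a xenograft read set, in [0, 1].
    divergence
        Per-base substitution rate between the synthetic human-like and
        mouse-like references, in [0, 1].
    planted_cnv
        Map gene id -> true integer copy number for the tumor sample.
    spectrum
        12-class substitution probability vector (sums to 1).
    plasma_slope, plasma_intercept
        True linear-model coefficients of the CCND1/CDKN2A ratio on
        log10 EBV load.
    plasma_noise_sd
        Residual standard deviation of the ratio around the linear model.
        The default (8.7) is derived from the target Pearson correlation of
        0.576 over a log-uniform load range of 5e3-4e5 copies/ml:
        r = s/sqrt(s^2 + sd^2) with signal sd s = slope * width/sqrt(12).
    qpcr_efficiency
        Per-cycle amplification efficiency in (0, 1]; 1 means perfect
        doubling.
    n_normals
        Size of the normal-karyotype WBC panel used as diploid reference.
    """

    seed: int = 0
    n_genes: int = 200
    depth: float = 100.0
    contamination_fraction: float = 0.2
    divergence: float = 0.1
    planted_cnv: dict[str, int] = field(default_factory=dict)
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    plasma_slope: float = 11.11
    plasma_intercept: float = -36.93
    plasma_noise_sd: float = 8.7
    qpcr_efficiency: float = 1.0
    n_normals: int = 4

    # synthetic genome / read-set geometry
    genome_length: int = 20_000
    chrx_length: int = 10_000
    read_length: int = 100
    n_reads: int = 5_000
    read_error_rate: float = 0.01

    # variant-table planted filter-failure fractions
    frac_fail_coverage: float = 0.1
    frac_fail_vaf: float = 0.1
    frac_fail_maf: float = 0.1

    # plasma cohort shape (high-EBV-load cohort defaults)
    plasma_load_range: tuple[float, float] = (5_000.0, 400_000.0)
    cdkn2a_loss_max_prob: float = 0.7
    cdkn2a_homdel_prob: float = 0.05
    cdkn2a_homdel_cn: float = 0.05
    plasma_ratio_floor: float = 0.01
    plasma_cn_noise_sd: float = 0.1

    # qPCR measurement model
    qpcr_replicates: int = 3
    qpcr_ct_noise_sd: float = 0.0
    qpcr_base_ct: dict[str, float] = field(
        default_factory=lambda: {"CCND1": 26.0, "CDKN2A": 27.0, "RAD52": 25.0}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ConfigurationError(
                f"contamination_fraction must lie in [0, 1], got "
                f"{self.contamination_fraction}"
            )
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigurationError(
                f"divergence must lie in [0, 1], got {self.divergence}"
            )
        if not 0.0 < self.qpcr_efficiency <= 1.0:
            raise ConfigurationError(
                f"qpcr_efficiency must lie in (0, 1], got {self.qpcr_efficiency}"
            )
        if set(self.spectrum) != set(SUBSTITUTION_CLASSES):
            missing = set(SUBSTITUTION_CLASSES) - set(self.spectrum)
            extra = set(self.spectrum) - set(SUBSTITUTION_CLASSES)
            raise ConfigurationError(
                f"spectrum must cover exactly the 12 substitution classes "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        total = sum(self.spectrum.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(f"spectrum must sum to 1, got {total}")
        if any(p < 0 for p in self.spectrum.values()):
            raise ConfigurationError("spectrum probabilities must be >= 0")
        for gene, cn in self.planted_cnv.items():
            if cn < 0 or int(cn) != cn:
                raise ConfigurationError(
                    f"planted copy number for {gene} must be a non-negative "
                    f"integer, got {cn}"
                )
        if self.genome_length <= 0 or self.chrx_length <= 0:
            raise ConfigurationError("genome lengths must be positive")
        if self.n_normals < 1:
            raise ConfigurationError("n_normals must be >= 1")
        lo, hi = self.plasma_load_range
        if lo <= 0 or hi <= lo:
            raise ConfigurationError(
                f"plasma_load_range must be a positive increasing interval, "
                f"got {self.plasma_load_range}"
            )

    # named sub-streams ---------------------------------------------------
    _STREAMS = (
        "reference",
        "reads",
        "coverage",
        "variants",
        "plasma",
        "qpcr",
        "expression",
    )

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-output random generator."""
        if stream not in self._STREAMS:
            raise ConfigurationError(f"unknown RNG stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), self._STREAMS.index(stream)])
        )

    # (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plasma_load_range"] = list(self.plasma_load_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "plasma_load_range" in d:
            d["plasma_load_range"] = tuple(d["plasma_load_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
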