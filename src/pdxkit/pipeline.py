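"""End-to-end pipeline runner with a machine-readable run manifest.

Stages run in dependency order: simulate -> xenofilter -> coverage ->
cnv / variants / expression -> plasma biomarker. The manifest records the
package version, configuration, seed, per-stage status and the SHA-256 of
every output file, which together suffice to reproduce a run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from . import expression as expr
from . import io as pio
from . import plasma as pl
from . import simulate as sim
from . import variants as var
from . import wescnv, xenofilter
from .config import SimulationConfig
from .errors import PdxkitError, ValidationError

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: SimulationConfig | dict | str | Path, outdir) -> dict:
    """Run every stage on a synthetic cohort and write all outputs.

    ``config`` is a :class:`SimulationConfig`, a dict of its fields, or a
    path to a YAML file. Returns the manifest (also written to
    ``manifest.json``). Any stage failure aborts with the stage name and
    cause; outputs written up to that point are listed as partial.
    """
    if isinstance(config, (str, Path)):
        if not Path(config).exists():
            raise ValidationError(f"config file not found: {config}")
        config = SimulationConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "pdxkit",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = "completed"
        for name, path in outputs.items():
            manifest["outputs"][name] = {
                "path": str(path.relative_to(outdir)),
                "sha256": _sha256(path),
            }

    stage = "simulate"
    try:
        human, mouse = sim.gen_reference_pair(config)
        reads = sim.gen_reads(config, (human, mouse))
        models = sim.gen_gene_models(config)
        truth = config.planted_cnv
        tumor_counts, normal_counts = sim.gen_coverage(config, models, truth)
        variants_df, _ = sim.gen_variant_table(
            config, {"PDX-1": 60, "PDX-2": 60}
        )
        cohort = sim.gen_plasma_cohort(config)
        expr_counts, de_labels = sim.gen_expression(config)

        pio.write_fasta(outdir / "human.fa", human)
        pio.write_fasta(outdir / "mouse.fa", mouse)
        pio.write_reads_fastq(outdir / "reads.fastq", reads)
        pio.write_read_labels(outdir / "reads.labels.json", reads)
        pio.write_bed(outdir / "genes.bed", models)
        pio.write_counts_tsv(outdir / "tumor_counts.tsv", tumor_counts)
        pio.write_counts_tsv(outdir / "normal_counts.tsv", normal_counts)
        pio.write_variant_table(outdir / "variants.tsv", variants_df)
        pio.write_plasma_csv(outdir / "plasma.csv", cohort)
        pio.write_counts_tsv(outdir / "expression_counts.tsv", expr_counts)
        record(stage, {
            "human_reference": outdir / "human.fa",
            "mouse_reference": outdir / "mouse.fa",
            "reads": outdir / "reads.fastq",
            "read_labels": outdir / "reads.labels.json",
            "gene_models": outdir / "genes.bed",
            "tumor_counts": outdir / "tumor_counts.tsv",
            "normal_counts": outdir / "normal_counts.tsv",
            "variants": outdir / "variants.tsv",
            "plasma": outdir / "plasma.csv",
            "expression_counts": outdir / "expression_counts.tsv",
        })

        stage = "xenofilter"
        xf_dir = outdir / "xenofilter"
        xenofilter.partition_reads(
            outdir / "reads.fastq", outdir / "human.fa", outdir / "mouse.fa",
            xf_dir, k=15, margin=1,
        )
        record(stage, {
            "reads_human": xf_dir / "human.fastq",
            "reads_mouse": xf_dir / "mouse.fastq",
            "reads_ambiguous": xf_dir / "ambiguous.fastq",
            "xenofilter_summary": xf_dir / "summary.json",
        })

        stage = "cnv"
        tumor_density = wescnv.read_density(tumor_counts, models)
        normal_density = normal_counts.apply(
            lambda col: wescnv.read_density(col, models)
        )
        baseline = wescnv.panel_baseline(normal_density)
        profile = wescnv.to_copy_number(tumor_density, baseline, models)
        calls = wescnv.call_gain_loss(profile)
        pio.write_profile_tsv(outdir / "cnv_profile.tsv", profile, calls)
        record(stage, {"cnv_profile": outdir / "cnv_profile.tsv"})

        stage = "variants"
        retained, removal = var.filter_variants(variants_df)
        spectrum = var.substitution_spectrum(retained)
        pio.write_variant_table(outdir / "variants_retained.tsv", retained)
        pio.write_json(outdir / "spectrum.json", {
            "counts": spectrum.counts,
            "percentages": spectrum.percentages,
            "total": spectrum.total,
            "removal": removal,
            "per_sample": var.per_sample_counts(retained),
        })
        record(stage, {
            "variants_retained": outdir / "variants_retained.tsv",
            "spectrum": outdir / "spectrum.json",
        })

        stage = "expression"
        t_cols = [c for c in expr_counts.columns if c.startswith("T")]
        c_cols = [c for c in expr_counts.columns if c.startswith("C")]
        deg = expr.call_deg(expr_counts[t_cols], expr_counts[c_cols])
        deg.to_csv(outdir / "deg.tsv", sep="\t", float_format=pio.FLOAT_FORMAT)
        pio.write_json(outdir / "deg_summary.json", expr.deg_summary(deg))
        record(stage, {
            "deg": outdir / "deg.tsv",
            "deg_summary": outdir / "deg_summary.json",
        })

        stage = "biomarker"
        fit = pl.fit_load_regression(cohort)
        calls_b = [
            pl.classify_candidate(row.patient_id, row.ratio)
            for row in cohort.itertuples()
        ]
        pio.write_json(outdir / "biomarker.json", {
            "fit": {
                "slope": fit.slope, "intercept": fit.intercept,
                "pearson_r": fit.pearson_r, "n": fit.n,
            },
            "cutoff": 4.0,
            "calls": [
                {"patient_id": c.patient_id, "ratio": c.ratio, "candidate": c.candidate}
                for c in calls_b
            ],
        })
        record(stage, {"biomarker": outdir / "biomarker.json"})
    except PdxkitError as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        manifest["partial"] = True
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PdxkitError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
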