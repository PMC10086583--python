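"""End-to-end cohort pipeline.

Orchestrates the study's analysis shape: ASCN segments -> scar scores +
CIN features + HRR-CIN -> cut-off inference (or published fixed
thresholds) -> per-sample HRD status -> optional SARC-HRD signature
scores; writes a per-sample table, a cut-off report and a manifest.

The published fixed thresholds (HRD score >= 32, LOH >= 10) are available
through ``cutoff_mode="fixed"`` for cross-cohort application.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cin_features import CINParams, cin_profile
from .cutoff_inference import (
    bootstrap_cutoff_ci,
    classify_by_cutoff,
    fit_two_component_mixture,
    roc_youden,
)
from .expression_signature import SARC_HRD, signature_score
from .reference_io import (
    hrr_gene_catalog,
    load_genome_build,
    read_ascn_segments,
    read_expression,
    read_l2r_segments,
)
from .scar_signatures import ScarParams, score_cohort

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

#: published fixed thresholds
HRD_CUTOFF_FIXED = 32
LOH_CUTOFF_FIXED = 10


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PipelineConfig(BaseModel):
    segments: Path
    gene_cn_segments: Path | None = None
    expression: Path | None = None
    genome: str = "hg38"
    out_dir: Path = Path("hrdscape_out")
    cutoff_mode: str = "infer"  # infer | fixed
    hrd_cutoff: float = Field(default=HRD_CUTOFF_FIXED, gt=0)
    seed: int = 0
    n_boot: int = 200
    scar_params: dict = {}
    cin_params: dict = {}

    @field_validator("cutoff_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("infer", "fixed"):
            raise ValueError("cutoff_mode must be 'infer' or 'fixed'")
        return v


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if not Path(config.segments).exists():
        raise FileNotFoundError(f"segments file {config.segments} not found")
    genome = load_genome_build(config.genome)
    segments = read_ascn_segments(config.segments)
    gene_cn = (
        read_l2r_segments(config.gene_cn_segments)
        if config.gene_cn_segments
        else None
    )
    expr = read_expression(config.expression) if config.expression else None
    return genome, segments, gene_cn, expr


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the full cohort analysis; returns the per-sample table.

    Writes ``samples.tsv``, ``cutoffs.json``, ``cytoband_cin.tsv`` and
    ``manifest.json`` under ``config.out_dir``.  Any stage failure aborts
    with a stage-tagged error and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        genome, segments, gene_cn, expr = _load_inputs(config)
        scar_params = ScarParams(**config.scar_params)
        cin_params = CINParams(**config.cin_params)

        table = _score_stage(segments, genome, scar_params)
        catalog = None
        if gene_cn is not None:
            catalog = hrr_gene_catalog(genome)
            cin_tbl, band_tbl = _cin_stage(
                gene_cn, genome, cin_params, catalog
            )
            table = table.merge(cin_tbl, on="sample", how="left")
            band_path = out_dir / "cytoband_cin.tsv"
            band_tbl.to_csv(band_path, sep="\t", index=False)
            written.append(band_path)

        cutoff_report = _cutoff_stage(config, table)
        table["hrd_status"] = classify_by_cutoff(
            table["hrd"], cutoff_report["hrd_cutoff"]
        )

        if expr is not None:
            scores = _signature_stage(expr)
            table = table.merge(
                scores.rename("signature_score"),
                left_on="sample", right_index=True, how="left",
            )

        samples_path = out_dir / "samples.tsv"
        table.to_csv(samples_path, sep="\t", index=False)
        written.append(samples_path)
        cutoff_path = out_dir / "cutoffs.json"
        cutoff_path.write_text(json.dumps(cutoff_report, indent=2))
        written.append(cutoff_path)
        manifest = {
            "hrdscape_version": __version__,
            "python": platform.python_version(),
            "genome": config.genome,
            "seed": config.seed,
            "cutoff_mode": config.cutoff_mode,
            "scar_params": scar_params.__dict__,
            "cin_params": cin_params.__dict__,
            "n_samples": int(table["sample"].nunique()),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        written.append(manifest_path)
        return table
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


@_stage("scars")
def _score_stage(segments, genome, scar_params):
    return score_cohort(segments, genome, scar_params)


@_stage("cin")
def _cin_stage(gene_cn, genome, cin_params, catalog):
    by_sample: dict[str, list] = {}
    for seg in gene_cn:
        by_sample.setdefault(seg.sample, []).append(seg)
    rows, bands = [], []
    for sample, segs in sorted(by_sample.items()):
        prof = cin_profile(segs, genome, cin_params, catalog)
        rows.append(prof.summary_row())
        band = prof.cytoband_counts.copy()
        band.insert(0, "sample", sample)
        bands.append(band)
    return pd.DataFrame(rows), pd.concat(bands, ignore_index=True)


@_stage("cutoff")
def _cutoff_stage(config: PipelineConfig, table: pd.DataFrame) -> dict:
    if config.cutoff_mode == "fixed":
        return {
            "mode": "fixed",
            "hrd_cutoff": float(config.hrd_cutoff),
            "loh_cutoff": float(LOH_CUTOFF_FIXED),
        }
    if "hrr_cin" not in table.columns or table["hrr_cin"].isna().all():
        raise ValueError(
            "cutoff inference needs HRR-CIN scores; provide gene-level "
            "copy-number segments or use cutoff_mode='fixed'"
        )
    values = table["hrr_cin"].dropna().to_numpy(dtype=float)
    fit = fit_two_component_mixture(values, seed=config.seed)
    if not fit.converged or fit.cutoff is None:
        raise ValueError("HRR-CIN mixture fit did not converge")
    ci_low, ci_high = bootstrap_cutoff_ci(
        values, n_boot=config.n_boot, seed=config.seed
    )
    status = classify_by_cutoff(table["hrr_cin"].to_numpy(dtype=float),
                                fit.cutoff)
    roc_hrd = roc_youden(status == "high", table["hrd"].to_numpy(dtype=float))
    roc_loh = roc_youden(
        classify_by_cutoff(table["hrd"].to_numpy(dtype=float),
                           roc_hrd.optimal_cutpoint) == "high",
        table["loh"].to_numpy(dtype=float),
    )
    return {
        "mode": "infer",
        "hrr_cin_mixture": {
            "means": fit.means,
            "sds": fit.sds,
            "weights": fit.weights,
            "loglik": fit.loglik,
        },
        "hrr_cin_cutoff": fit.cutoff,
        "hrr_cin_cutoff_ci": [ci_low, ci_high],
        "hrd_cutoff": float(roc_hrd.optimal_cutpoint),
        "hrd_roc_auc": roc_hrd.auc,
        "loh_cutoff": float(roc_loh.optimal_cutpoint),
        "loh_roc_auc": roc_loh.auc,
    }


@_stage("signature")
def _signature_stage(expr):
    return signature_score(expr, SARC_HRD)
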