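"""End-to-end orchestration: simulate (or load) -> quantify -> both
differential-expression routes -> splicing per contrast -> drug-response
calls, with a manifest recording config, seeds, and per-stage row counts.

Every stochastic stage receives its own seed derived deterministically
from the master seed (``hash(master, stage name)``), so any stage can be
re-run in isolation and reproduces its output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .diffexpr import anova_de, sam_de, top_n_overlap
from .models import (
    CountTable,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
    transcript_lengths,
)
from .published import TABLE_NAMES, load_fold_table
from .quantify import filter_expressed, rpkm
from .response import ResponseConfig, classify_table, signed_log2_columns
from .simulate import SimConfig, simulate_dataset
from .splicing import aspire_scan, junction_fraction

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("D", "N"), ("D_T1", "N"), ("D_T2", "N"))


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``sim`` (a simulation block) or ``inputs`` (paths to
    annotation, count tables, and a design table) must be set.  All
    thresholds default to the pipeline's canonical values: RPKM filters of
    1.0 (ANOVA route), 0.5 (SAM route) and 3.0 (splicing gate), fold
    cutoff 1.5, p cutoff 0.05, FDR cutoff 0.25, delta-I cutoff 0.2.
    """

    outdir: str = "retseq_run"
    seed: int = 1
    sim: SimConfig | None = None
    inputs: dict | None = None
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    rpkm_filter_anova: float = 1.0
    rpkm_filter_sam: float = 0.5
    rpkm_filter_splicing: float = 3.0
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    fdr_cutoff: float = 0.25
    delta_cutoff: float = 0.2
    anova_combine: str = "and"
    response: ResponseConfig = field(default_factory=ResponseConfig)
    top_n: int = 100

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValidationError(
                "config must set exactly one of a simulation block or real input paths"
            )


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if hasattr(obj, "__dict__"):
            return obj.__dict__
        return str(obj)

    payload = asdict(config)
    payload.pop("outdir", None)  # where the run lands is not part of the analysis
    text = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_inputs(inputs: dict):
    models = rio.read_refflat(inputs["annotation"])
    design = rio.read_design(inputs["design"])
    transcript_ct = rio.read_count_matrix(inputs["transcript_counts"], "transcript")
    exon_ct = rio.read_count_matrix(inputs["exon_counts"], "exon")
    junction_ct = rio.read_junction_counts(inputs["junction_counts"])
    catalog = rio.read_catalog(inputs["catalog"])
    return models, catalog, design, transcript_ct, exon_ct, junction_ct, None


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "stage_seeds": {},
        "versions": {"retseq": _package_version(), "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    t0 = time.time()

    if config.sim is not None:
        sim_seed = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        sim_cfg = SimConfig(**{**config.sim.__dict__, "seed": sim_seed})
        data = simulate_dataset(sim_cfg)
        models, catalog, design = data.models, data.catalog, data.design
        transcript_ct, exon_ct, junction_ct = (
            data.transcript_counts, data.exon_counts, data.junction_counts,
        )
        truth = data.truth
        rio.write_refflat(models, outdir / "annotation.refflat")
        rio.write_design(design, outdir / "design.tsv")
        rio.write_catalog(catalog, outdir / "catalog.tsv")
        rio.write_count_matrix(transcript_ct, outdir / "transcript_counts.tsv")
        rio.write_count_matrix(exon_ct, outdir / "exon_counts.tsv")
        rio.write_junction_counts(junction_ct, outdir / "junction_counts.tsv")
        rio.write_results(truth.transcripts, outdir / "truth_transcripts.tsv",
                          id_label="transcript_id")
        rio.write_results(truth.events, outdir / "truth_events.tsv", id_label="event_id")
    else:
        models, catalog, design, transcript_ct, exon_ct, junction_ct, truth = _load_inputs(
            config.inputs
        )
    manifest["stages"]["input"] = {
        "transcripts": len(transcript_ct.feature_ids),
        "exons": len(exon_ct.feature_ids),
        "junctions": len(junction_ct.feature_ids),
        "samples": len(design.sample_ids),
        "events": len(catalog),
    }

    # --- quantification -------------------------------------------------
    lengths = transcript_lengths(models)
    expr = rpkm(transcript_ct, lengths)
    rio.write_results(expr.values, outdir / "rpkm.tsv", id_label="transcript_id")
    expressed_anova = filter_expressed(expr, config.rpkm_filter_anova)
    expressed_sam = filter_expressed(expr, config.rpkm_filter_sam)
    manifest["stages"]["quantify"] = {
        "features": len(expr.feature_ids),
        "pass_anova_filter": len(expressed_anova),
        "pass_sam_filter": len(expressed_sam),
    }

    # --- differential expression, both routes ---------------------------
    expr_anova = ExpressionMatrix(expr.values.loc[expressed_anova], "rpkm")
    expr_sam = ExpressionMatrix(expr.values.loc[expressed_sam], "rpkm")
    de_tables = {}
    for case, control in config.contrasts:
        anova_res = anova_de(
            expr_anova, design, (case, control),
            fc_cutoff=config.fc_cutoff, p_cutoff=config.p_cutoff,
            combine=config.anova_combine,
        )
        sam_res = sam_de(
            expr_sam, design, (case, control),
            fc_cutoff=config.fc_cutoff, fdr_cutoff=config.fdr_cutoff,
            seed=stage_seed(config.seed, f"sam:{case}:{control}"),
        )
        tag = f"{case}_vs_{control}"
        rio.write_results(anova_res.table, outdir / f"de_anova_{tag}.tsv",
                          id_label="feature_id")
        rio.write_results(sam_res.table, outdir / f"de_sam_{tag}.tsv",
                          id_label="feature_id")
        de_tables[(case, control)] = (anova_res, sam_res)
        manifest["stages"][f"de_{tag}"] = {
            "anova_pass": int(anova_res.table["passes"].sum()),
            "sam_pass": int(sam_res.table["passes"].sum()),
        }

    # --- route concordance on the disease contrast ----------------------
    primary = config.contrasts[0]
    overlap = top_n_overlap(*de_tables[primary], n=config.top_n)
    rio.write_results(
        pd.DataFrame(
            [{"n": overlap.n, "only_anova": overlap.only_a,
              "only_sam": overlap.only_b, "shared": overlap.shared}]
        ),
        outdir / "overlap.tsv",
    )
    manifest["stages"]["overlap"] = {"shared": overlap.shared, "n": overlap.n}

    # --- splicing per contrast ------------------------------------------
    fractions = junction_fraction(junction_ct, exon_ct, models, catalog)
    tx_to_gene = {m.transcript_id: m.gene_id for m in models}
    gene_values = expr.values.rename(index=tx_to_gene).groupby(level=0).max()
    gene_expr = ExpressionMatrix(gene_values, "rpkm")
    event_tables = {}
    for case, control in config.contrasts:
        events = aspire_scan(
            junction_ct, exon_ct, catalog, gene_expr, design, (case, control),
            rpkm_cutoff=config.rpkm_filter_splicing,
            delta_cutoff=config.delta_cutoff,
            fdr_level=config.fdr_cutoff,
            seed=stage_seed(config.seed, f"splice:{case}:{control}"),
            fractions=fractions,
        )
        tag = f"{case}_vs_{control}"
        rio.write_results(events, outdir / f"events_{tag}.tsv", id_label="event_id")
        event_tables[(case, control)] = events
        manifest["stages"][f"events_{tag}"] = {
            "tested": int((events["status"] == "tested").sum()) if len(events) else 0,
            "passing": int(events["passes"].sum()) if len(events) else 0,
        }

    # --- drug-response classification -----------------------------------
    response_contrasts = {("D", "N"), ("D_T1", "N"), ("D_T2", "N")}
    if response_contrasts <= set(config.contrasts):
        folds = pd.DataFrame(
            {
                "d": de_tables[("D", "N")][0].table["signed_log2"],
                "t1": de_tables[("D_T1", "N")][0].table["signed_log2"],
                "t2": de_tables[("D_T2", "N")][0].table["signed_log2"],
            }
        ).dropna()
        calls = classify_table(folds, config.response)
        rio.write_results(calls, outdir / "calls.tsv")
        manifest["stages"]["response"] = {
            "features": len(folds),
            "calls": len(calls),
            "summary": {f"{k[0]}:{k[1]}": v for k, v in calls.attrs["summary"].items()},
        }

    # wall time is logged, not recorded: manifests must be byte-identical
    # across reruns of the same config+seed
    logger.info("pipeline finished in %.2fs", time.time() - t0)
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def _package_version() -> str:
    try:
        return metadata.version("retseq")
    except metadata.PackageNotFoundError:
        return "unknown"


def make_fixtures(outdir) -> list[Path]:
    """Write the published fold-change tables as standalone TSV fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in TABLE_NAMES:
        table = load_fold_table(name)
        path = outdir / f"folds_{name}.tsv"
        rio.write_results(table, path, id_label="gene_symbol")
        written.append(path)
    return written
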