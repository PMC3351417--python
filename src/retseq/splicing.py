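"""Reciprocal-isoform alternative-splicing detection from junction reads.

For each gene, every junction's count is normalized to the mean count of
all junction and exon features of that gene (the junction fraction f_j).
For a reciprocal isoform pair -- one isoform including a cassette exon
(supported by the flanking inclusion junctions) and one skipping it
(supported by the exclusion junction) -- the per-sample inclusion ratio is

    I = f_incl / (f_incl + f_excl)

and the splicing-change score for a contrast is

    delta_I = mean(I over case samples) - mean(I over control samples).

Because both members of a pair share the gene-mean normalizer, it cancels
exactly in I; I computed from raw counts equals I computed from fractions.
Events are gated on gene expression (RPKM cutoff, default 3.0), scored
with |delta_I| (cutoff 0.2 = a 20% change in exon inclusion), assigned
group-label permutation p-values, and corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diffexpr import label_assignments
from .models import (
    CountTable,
    ExpressionMatrix,
    GeneModel,
    ReciprocalPairCatalog,
    SampleDesign,
    ValidationError,
    feature_gene_map,
)

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 500  # enumerate all assignments when no more than this many exist


def junction_fraction(
    junction_counts: CountTable,
    exon_counts: CountTable,
    models: Iterable[GeneModel],
    catalog: ReciprocalPairCatalog | None = None,
) -> pd.DataFrame:
    """Per-sample junction fractions f_j = c_j / gene-mean feature count.

    The denominator for a junction is the mean count over all junction and
    exon features of its gene in that sample.  Genes with zero total
    coverage in a sample yield NaN fractions there.  Exclusion (skip)
    junctions belong to no single transcript model, so a catalog may be
    passed to assign them to their gene.
    """
    models = list(models)
    gene_of = feature_gene_map(models)
    if catalog is not None:
        for ev in catalog:
            for jid in (*ev.inclusion_junctions, *ev.exclusion_junctions):
                prev = gene_of.get(jid)
                if prev is not None and prev != ev.gene_id:
                    raise ValidationError(
                        f"junction {jid} assigned to two genes: {prev}, {ev.gene_id}"
                    )
                gene_of[jid] = ev.gene_id
    for fid in junction_counts.feature_ids:
        if fid not in gene_of:
            raise ValidationError(f"junction {fid} not assigned to any gene model")
    for fid in exon_counts.feature_ids:
        if fid not in gene_of:
            raise ValidationError(f"exon {fid} not assigned to any gene model")
    combined = pd.concat([junction_counts.counts, exon_counts.counts])
    combined = combined[~combined.index.duplicated()]
    genes = pd.Index([gene_of[f] for f in combined.index], name="gene_id")
    gene_means = combined.groupby(genes).mean()
    junction_genes = [gene_of[f] for f in junction_counts.feature_ids]
    denom = gene_means.loc[junction_genes].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = junction_counts.counts.to_numpy(dtype=float) / denom
    frac[:, :][np.broadcast_to(denom == 0, frac.shape)] = np.nan
    return pd.DataFrame(
        frac, index=junction_counts.counts.index, columns=junction_counts.counts.columns
    )


def inclusion_ratio(f_incl, f_excl):
    """I = f_incl / (f_incl + f_excl), in [0, 1]; NaN when both are 0."""
    f_incl = np.asarray(f_incl, dtype=float)
    f_excl = np.asarray(f_excl, dtype=float)
    total = f_incl + f_excl
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, f_incl / total, np.nan)
    return ratio if ratio.ndim else float(ratio)


def event_inclusion(
    fractions: pd.DataFrame,
    event,
    combine: str = "mean",
) -> pd.Series:
    """Per-sample inclusion ratio for one reciprocal pair.

    Multiple inclusion junctions are combined by the ``mean`` of their
    fractions (default) or their ``sum`` before the ratio; the exclusion
    side is combined the same way.
    """
    if combine not in ("mean", "sum"):
        raise ValidationError(f"unknown combine rule {combine!r}")
    missing = [
        j
        for j in (*event.inclusion_junctions, *event.exclusion_junctions)
        if j not in fractions.index
    ]
    if missing:
        raise ValidationError(f"{event.event_id}: junction(s) missing from table: {missing}")
    agg = np.nanmean if combine == "mean" else np.nansum
    with np.errstate(invalid="ignore"):
        f_in = agg(fractions.loc[list(event.inclusion_junctions)].to_numpy(), axis=0)
        f_ex = agg(fractions.loc[list(event.exclusion_junctions)].to_numpy(), axis=0)
    return pd.Series(inclusion_ratio(f_in, f_ex), index=fractions.columns)


def delta_i(i_case: Sequence[float], i_control: Sequence[float]) -> float:
    """Mean per-sample inclusion-ratio difference, case minus control."""
    i_case = np.asarray(i_case, dtype=float)
    i_control = np.asarray(i_control, dtype=float)
    if np.isnan(i_case).all() or np.isnan(i_control).all():
        raise ValidationError("delta_i needs at least one defined inclusion ratio per side")
    return float(np.nanmean(i_case) - np.nanmean(i_control))


def _permutation_pvalue(i_values: np.ndarray, n_case: int, assignments) -> float:
    """Exhaustive permutation p for |delta_I| over the given label assignments."""
    all_idx = np.arange(len(i_values))
    with np.errstate(invalid="ignore"):
        observed = abs(np.nanmean(i_values[:n_case]) - np.nanmean(i_values[n_case:]))
        hits = 0
        for a in assignments:
            case = np.asarray(a)
            ctrl = np.setdiff1d(all_idx, case)
            stat = abs(np.nanmean(i_values[case]) - np.nanmean(i_values[ctrl]))
            if stat >= observed - 1e-12:
                hits += 1
    return hits / len(assignments)


def aspire_scan(
    junction_counts: CountTable,
    exon_counts: CountTable,
    catalog: ReciprocalPairCatalog,
    expr: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    rpkm_cutoff: float = 3.0,
    delta_cutoff: float = 0.2,
    fdr_level: float = 0.25,
    n_perm: int | str = "exhaustive",
    combine: str = "mean",
    seed: int | None = None,
    models: Iterable[GeneModel] | None = None,
    fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every catalog event for differential exon inclusion.

    ``expr`` is gene-level (or one-transcript-per-gene) RPKM used for the
    expression gate: an event is analyzed only if its gene reaches
    ``rpkm_cutoff`` in at least one sample of the contrast.  Events with
    undefined inclusion in more than half the samples of either group, or
    zero junction coverage on one side, are excluded (``status`` column).

    Returns one row per analyzed event: per-group mean inclusion, delta_i,
    permutation p-value, BH FDR, coverage (total event junction reads over
    the contrast's samples), and ``passes``.
    """
    case, control = contrast
    case_samples = design.samples(case)
    ctrl_samples = design.samples(control)
    samples = case_samples + ctrl_samples
    n_case = len(case_samples)

    if fractions is None:
        if models is None:
            raise ValidationError("aspire_scan needs gene models (or precomputed fractions)")
        fractions = junction_fraction(junction_counts, exon_counts, models, catalog)
    fractions = fractions[samples]

    gene_expr = expr.subset_samples([s for s in samples if s in expr.sample_ids])
    expressed = set(
        gene_expr.values.index[(gene_expr.values.max(axis=1) >= rpkm_cutoff)]
    )

    n_total = len(samples)
    assignments = label_assignments(n_case, len(ctrl_samples))
    if n_perm == "exhaustive" or len(assignments) <= EXHAUSTIVE_LIMIT:
        chosen = assignments
    else:
        if seed is None:
            raise ValidationError("seed is mandatory for sampled permutations")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(assignments), size=int(n_perm))
        chosen = [assignments[i] for i in idx]

    rows = []
    for ev in catalog:
        if ev.gene_id not in expressed:
            rows.append({"event_id": ev.event_id, "gene_id": ev.gene_id,
                         "status": "below_rpkm_gate"})
            continue
        i_all = event_inclusion(fractions, ev, combine=combine)
        i_case = i_all[case_samples].to_numpy()
        i_ctrl = i_all[ctrl_samples].to_numpy()
        junctions = list(ev.inclusion_junctions) + list(ev.exclusion_junctions)
        cov_by_sample = junction_counts.counts.reindex(junctions)[samples].sum(axis=0)
        coverage = int(cov_by_sample.sum())
        if cov_by_sample[case_samples].sum() == 0 or cov_by_sample[ctrl_samples].sum() == 0:
            logger.info("event %s excluded: zero junction coverage in a group", ev.event_id)
            rows.append({"event_id": ev.event_id, "gene_id": ev.gene_id,
                         "coverage": coverage, "status": "zero_coverage"})
            continue
        if (np.isnan(i_case).sum() > len(i_case) / 2) or (
            np.isnan(i_ctrl).sum() > len(i_ctrl) / 2
        ):
            rows.append({"event_id": ev.event_id, "gene_id": ev.gene_id,
                         "coverage": coverage, "status": "undefined_inclusion"})
            continue
        d_i = delta_i(i_case, i_ctrl)
        p = _permutation_pvalue(
            np.concatenate([i_case, i_ctrl]), n_case, chosen
        )
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "i_case": float(np.nanmean(i_case)),
                "i_control": float(np.nanmean(i_ctrl)),
                "delta_i": d_i,
                "p_value": p,
                "coverage": coverage,
                "status": "tested",
            }
        )
    result = pd.DataFrame(rows).set_index("event_id") if rows else pd.DataFrame(
        columns=["gene_id", "status"]
    )
    if len(result):
        tested = result["status"] == "tested"
        result["fdr"] = np.nan
        if tested.any():
            _, q, _, _ = multipletests(
                result.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
            )
            result.loc[tested, "fdr"] = q
            result["passes"] = (
                tested
                & (result["delta_i"].abs() >= delta_cutoff)
                & (result["fdr"] <= fdr_level)
            ).fillna(False)
        else:
            result["passes"] = False
    return result
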