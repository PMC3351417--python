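"""RPKM quantification, log transform, expression filters, and exon-to-gene
summaries.

RPKM (reads per kilobase of exon model per million mapped reads) for
feature *f* in sample *s* is

    RPKM_fs = 1e9 * C_fs / (N_s * L_f)

where C is the read count, N_s the per-sample total of aligned reads
(``CountTable.library_sizes``, not the column sum of a filtered table) and
L_f the exon-model length in bases.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    CountTable,
    ExpressionMatrix,
    GeneModel,
    SampleDesign,
    ValidationError,
)

FILTER_RULES = ("any_sample", "all_samples", "group_mean")


def rpkm(counts: CountTable, lengths: Mapping[str, int] | pd.Series) -> ExpressionMatrix:
    """Length- and depth-normalize counts to RPKM."""
    lengths = pd.Series(lengths)
    missing = [f for f in counts.feature_ids if f not in lengths.index]
    if missing:
        raise ValidationError(f"missing exon-model length for feature(s): {missing[:5]}")
    L = lengths.reindex(counts.feature_ids).astype(float)
    if (L <= 0).any():
        bad = list(L.index[L <= 0])[:5]
        raise ValidationError(f"non-positive length for feature(s): {bad}")
    N = counts.library_sizes.astype(float)
    values = 1e9 * counts.counts.div(N, axis=1).div(L, axis=0)
    return ExpressionMatrix(values, scale="rpkm")


def log_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(RPKM + offset); strictly monotone and invertible given offset."""
    if expr.scale != "rpkm":
        raise ValidationError("log_transform expects an RPKM-scale matrix")
    if offset <= 0:
        raise ValidationError("offset must be positive")
    return ExpressionMatrix(np.log2(expr.values + offset), scale="log2", offset=offset)


def inverse_log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Recover the RPKM-scale matrix from a log2 matrix using its stored offset."""
    if expr.scale != "log2":
        raise ValidationError("inverse_log_transform expects a log2-scale matrix")
    return ExpressionMatrix(np.exp2(expr.values) - expr.offset, scale="rpkm")


def filter_expressed(
    expr: ExpressionMatrix,
    cutoff: float,
    rule: str = "any_sample",
    design: SampleDesign | None = None,
) -> list[str]:
    """Feature ids whose RPKM satisfies ``>= cutoff`` under ``rule``.

    Rules: ``any_sample`` (default; max over samples), ``all_samples``
    (min over samples), ``group_mean`` (any group mean; needs a design).
    The comparison is inclusive and the input ordering is preserved.
    """
    if expr.scale != "rpkm":
        raise ValidationError("filter_expressed expects an RPKM-scale matrix")
    if rule not in FILTER_RULES:
        raise ValidationError(f"unknown filter rule {rule!r}; choose from {FILTER_RULES}")
    if rule == "any_sample":
        keep = expr.values.max(axis=1) >= cutoff
    elif rule == "all_samples":
        keep = expr.values.min(axis=1) >= cutoff
    else:
        if design is None:
            raise ValidationError("group_mean rule requires a design")
        group_means = pd.DataFrame(
            {g: expr.values[design.samples(g)].mean(axis=1) for g in design.groups}
        )
        keep = group_means.max(axis=1) >= cutoff
    return list(expr.values.index[keep])


def gene_exon_summary(
    exon_expr: ExpressionMatrix,
    models: Iterable[GeneModel],
    mode: str = "average",
    offset: float = 1.0,
) -> ExpressionMatrix:
    """Summarize exon-level RPKM to one log2 value per gene.

    The gene value is ``log2(mode over its exons of exon RPKM + offset)``
    with mode ``average`` or ``maximum``.  Exon features are mapped to
    genes through the models' canonical exon ids.
    """
    if exon_expr.scale != "rpkm":
        raise ValidationError("gene_exon_summary expects an RPKM-scale exon matrix")
    if mode not in ("average", "maximum"):
        raise ValidationError(f"unknown summary mode {mode!r}")
    gene_of: dict[str, str] = {}
    for m in models:
        for eid in m.exon_ids():
            gene_of[eid] = m.gene_id
    unmapped = [f for f in exon_expr.feature_ids if f not in gene_of]
    if unmapped:
        raise ValidationError(f"exon feature(s) not in any model: {unmapped[:5]}")
    groups = exon_expr.values.groupby(
        pd.Index([gene_of[f] for f in exon_expr.feature_ids], name="gene_id")
    )
    summarized = groups.mean() if mode == "average" else groups.max()
    return ExpressionMatrix(np.log2(summarized + offset), scale="log2", offset=offset)
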