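"""Readers and writers for annotation, count, and result formats.

All tabular formats are TSV; every reader transparently accepts
gzip-compressed files.  Writers emit deterministic column order and fixed
decimal formatting so outputs are diffable.  Duplicate features are
rejected, never silently merged.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    CountTable,
    GeneModel,
    ReciprocalEvent,
    ReciprocalPairCatalog,
    SampleDesign,
    ValidationError,
    junction_feature_id,
)

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Raised when a file does not conform to its dialect."""


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# refFlat / GTF gene models
# ---------------------------------------------------------------------------

_REFFLAT_NCOL = 11


def _parse_comma_list(text: str, line_no: int, what: str) -> tuple[int, ...]:
    items = [t for t in text.strip().split(",") if t != ""]
    try:
        return tuple(int(t) for t in items)
    except ValueError as exc:
        raise ParseError(f"line {line_no}: malformed {what} list {text!r}") from exc


def read_refflat(path) -> list[GeneModel]:
    """Read gene models from a UCSC refFlat file.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (0-based starts, exclusive
    ends, comma-terminated lists).
    """
    models: list[GeneModel] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _REFFLAT_NCOL:
                raise ParseError(
                    f"line {line_no}: expected {_REFFLAT_NCOL} columns, got {len(fields)}"
                )
            (gene, name, chrom, strand, _tx_start, _tx_end,
             cds_start, cds_end, exon_count, starts_s, ends_s) = fields
            try:
                n_exons = int(exon_count)
            except ValueError as exc:
                raise ParseError(f"line {line_no}: bad exonCount {exon_count!r}") from exc
            starts = _parse_comma_list(starts_s, line_no, "exonStarts")
            ends = _parse_comma_list(ends_s, line_no, "exonEnds")
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ParseError(
                    f"line {line_no}: exonCount {n_exons} does not match list lengths "
                    f"({len(starts)} starts, {len(ends)} ends)"
                )
            exons = tuple(sorted(zip(starts, ends)))
            try:
                models.append(
                    GeneModel(
                        gene_id=gene,
                        transcript_id=name,
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        cds_start=int(cds_start),
                        cds_end=int(cds_end),
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
    return models


def write_refflat(models: Iterable[GeneModel], path) -> None:
    with _open_text(path, "wt") as handle:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            cds_start = m.cds_start if m.cds_start is not None else m.tx_start
            cds_end = m.cds_end if m.cds_end is not None else m.tx_end
            handle.write(
                "\t".join(
                    [
                        m.gene_id, m.transcript_id, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        str(cds_start), str(cds_end),
                        str(len(m.exons)), starts, ends,
                    ]
                )
                + "\n"
            )


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from an Ensembl-dialect GTF (exon features grouped
    by ``transcript_id``)."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tx = feat.attributes.get("transcript_id", [None])[0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        if tx is None:
            raise ParseError(f"GTF exon without transcript_id at {feat.seqid}:{feat.start}")
        rec = by_tx.setdefault(
            tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based inclusive; convert to 0-based half-open.
        rec["exons"].append((feat.start - 1, feat.end))
    models = []
    for tx, rec in by_tx.items():
        models.append(
            GeneModel(
                gene_id=rec["gene"],
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in ("+", "-") else "+",
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return models


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    import warnings

    with _open_text(path) as handle:
        with warnings.catch_warnings():
            # a row wider than the header makes pandas silently invent an
            # index; treat that as the dialect violation it is
            warnings.simplefilter("error", pd.errors.ParserWarning)
            try:
                df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, index_col=False)
            except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
                raise ParseError(f"malformed table: {exc}") from exc
    return df


def _to_numeric(df: pd.DataFrame, integer: bool) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().all():
            bad = converted.index[converted.isna() & df[col].notna()]
            row = bad[0]
            raise ParseError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        out[col] = converted
    result = pd.DataFrame(out, index=df.index)
    if integer:
        as_int = result.round().astype(np.int64)
        if not np.allclose(result.fillna(0).to_numpy(), as_int.to_numpy()):
            raise ParseError("expected integer counts, found fractional values")
        return as_int
    return result


def read_count_matrix(
    path, feature_kind: str, library_sizes: pd.Series | None = None
) -> CountTable:
    """Read a features x samples TSV of integer counts.

    First column is the feature id, the header row carries sample ids.
    When ``library_sizes`` is not supplied the column sums are used (i.e.
    the table is taken to be the whole library).
    """
    df = _read_tsv(path)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    counts = _to_numeric(df, integer=True)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
        if (library_sizes <= 0).any():
            raise ParseError("sample with zero total counts and no explicit library size")
    return CountTable(counts, library_sizes, feature_kind)


def write_count_matrix(table: CountTable, path, id_label: str = "feature_id") -> None:
    with _open_text(path, "wt") as handle:
        table.counts.to_csv(handle, sep="\t", index_label=id_label)


def read_junction_counts(path, library_sizes: pd.Series | None = None) -> CountTable:
    """Read a junction count TSV: columns ``chrom``, ``donor_end``,
    ``acceptor_start``, then one count column per sample.

    Junction ids are canonicalized as ``chrom:donor_end-acceptor_start``.
    Duplicate junction rows are an error (no silent summing).
    """
    df = _read_tsv(path)
    needed = ["chrom", "donor_end", "acceptor_start"]
    if list(df.columns[:3]) != needed:
        raise ParseError(
            f"junction table must start with columns {needed}, got {list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise ParseError("junction table has no sample columns")
    coords = _to_numeric(df[["donor_end", "acceptor_start"]], integer=True)
    ids = [
        junction_feature_id(c, d, a)
        for c, d, a in zip(df["chrom"], coords["donor_end"], coords["acceptor_start"])
    ]
    dup = pd.Index(ids).duplicated()
    if dup.any():
        raise ValidationError(f"duplicate junction row: {ids[int(np.flatnonzero(dup)[0])]}")
    counts = _to_numeric(df[sample_cols], integer=True)
    counts.index = pd.Index(ids, name="junction_id")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).clip(lower=1)
    return CountTable(counts, library_sizes, "junction")


def write_junction_counts(table: CountTable, path) -> None:
    if table.feature_kind != "junction":
        raise ValidationError("write_junction_counts requires a junction table")
    rows = []
    for fid in table.feature_ids:
        chrom, span = fid.rsplit(":", 1)
        donor, acceptor = span.split("-")
        rows.append((chrom, int(donor), int(acceptor)))
    meta = pd.DataFrame(rows, columns=["chrom", "donor_end", "acceptor_start"])
    out = pd.concat([meta, table.counts.reset_index(drop=True)], axis=1)
    with _open_text(path, "wt") as handle:
        out.to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results, designs, catalogs
# ---------------------------------------------------------------------------


def write_results(table: pd.DataFrame, path, id_label: str | None = None) -> None:
    """Write any results table as TSV with fixed decimal formatting."""
    with _open_text(path, "wt") as handle:
        table.to_csv(
            handle,
            sep="\t",
            float_format=FLOAT_FORMAT,
            index=id_label is not None,
            index_label=id_label,
        )


def read_results(path, index_col: str | None = None) -> pd.DataFrame:
    with _open_text(path) as handle:
        return pd.read_csv(handle, sep="\t", comment="#", index_col=0 if index_col else None)


def read_design(path) -> SampleDesign:
    df = _read_tsv(path)
    needed = {"sample_id", "group", "replicate"}
    if not needed <= set(df.columns):
        raise ParseError(f"design table must have columns {sorted(needed)}")
    df["replicate"] = _to_numeric(df[["replicate"]], integer=True)["replicate"]
    return SampleDesign(df[["sample_id", "group", "replicate"]])


def write_design(design: SampleDesign, path) -> None:
    with _open_text(path, "wt") as handle:
        design.table.to_csv(handle, sep="\t", index=False)


def read_catalog(path) -> ReciprocalPairCatalog:
    """Read a reciprocal-pair catalog TSV with columns ``event_id``,
    ``gene_id``, ``inclusion_junctions``, ``exclusion_junctions`` (the
    junction lists comma-separated)."""
    df = _read_tsv(path)
    needed = {"event_id", "gene_id", "inclusion_junctions", "exclusion_junctions"}
    if not needed <= set(df.columns):
        raise ParseError(f"catalog must have columns {sorted(needed)}")
    events = [
        ReciprocalEvent(
            event_id=row.event_id,
            gene_id=row.gene_id,
            inclusion_junctions=tuple(row.inclusion_junctions.split(",")),
            exclusion_junctions=tuple(row.exclusion_junctions.split(",")),
        )
        for row in df.itertuples()
    ]
    return ReciprocalPairCatalog(events)


def write_catalog(catalog: ReciprocalPairCatalog, path) -> None:
    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "inclusion_junctions": ",".join(ev.inclusion_junctions),
            "exclusion_junctions": ",".join(ev.exclusion_junctions),
        }
        for ev in catalog
    ]
    with _open_text(path, "wt") as handle:
        pd.DataFrame(rows).to_csv(handle, sep="\t", index=False)
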