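"""Core in-memory containers for the analysis pipeline.

Coordinates are 0-based half-open throughout (the native refFlat
convention); conversion to 1-based inclusive display coordinates happens
only at export time.  A splice junction is identified by
``(chrom, donor_end, acceptor_start)`` without strand -- strand is a
property of the gene, not of the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("N", "D", "D_T1", "D_T2")
"""Experimental groups: nondiabetic control, diabetic, diabetic treated
with the RAGE inhibitor (T1), diabetic treated with the p38 MAPK
inhibitor (T2)."""

FEATURE_KINDS = ("transcript", "gene", "exon", "junction")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def junction_feature_id(chrom: str, donor_end: int, acceptor_start: int) -> str:
    """Canonical junction identifier ``chrom:donor_end-acceptor_start``."""
    return f"{chrom}:{donor_end}-{acceptor_start}"


def exon_feature_id(transcript_id: str, index: int) -> str:
    """Canonical exon identifier within a transcript (0-based exon index)."""
    return f"{transcript_id}:e{index:03d}"


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered exons of one transcript on a genome.

    ``exons`` are ``(start, end)`` half-open intervals sorted by start and
    non-overlapping.  Junctions are derived from adjacent exon boundaries,
    so a contiguous transcript with *k* exons has *k - 1* junctions.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({start}, {end}) has end <= start"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end

    @property
    def exon_model_length(self) -> int:
        """Total exonic length in bases (the L of RPKM)."""
        return sum(end - start for start, end in self.exons)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor_end, acceptor_start) pairs between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def exon_ids(self) -> tuple[str, ...]:
        return tuple(exon_feature_id(self.transcript_id, i) for i in range(len(self.exons)))

    def junction_ids(self) -> tuple[str, ...]:
        return tuple(junction_feature_id(self.chrom, d, a) for d, a in self.junctions)

    def to_display_coords(self) -> tuple[tuple[int, int], ...]:
        """Exons in 1-based inclusive display coordinates."""
        return tuple((start + 1, end) for start, end in self.exons)

    @staticmethod
    def from_display_coords(coords: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
        """Inverse of :meth:`to_display_coords`."""
        return tuple((start - 1, end) for start, end in coords)


@dataclass
class SampleDesign:
    """Assignment of samples to the four experimental groups.

    Backed by a DataFrame with columns ``sample_id``, ``group``,
    ``replicate``.  Statistical routines require at least two replicates
    per group they touch; a full design covers all four groups.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id in design: {dup}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group(s) in design: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def balanced(cls, n_replicates: int, groups: Sequence[str] = GROUPS) -> "SampleDesign":
        rows = [
            {"sample_id": f"{g}_{r + 1}", "group": g, "replicate": r + 1}
            for g in groups
            for r in range(n_replicates)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples(self, group: str) -> list[str]:
        if group not in set(self.table["group"]):
            raise ValidationError(f"group {group!r} not present in design")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])


@dataclass
class CountTable:
    """Integer read counts, features x samples, plus library sizes.

    ``library_sizes`` are per-sample totals of aligned reads (the N of
    RPKM), which may exceed the column sums when the table covers only a
    subset of the library.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.feature_kind!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample id in count table")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValidationError("negative count in count table")
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValidationError(f"missing library size for sample(s): {missing}")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        self.library_sizes = self.library_sizes.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(
            self.counts[list(sample_ids)].copy(),
            self.library_sizes[list(sample_ids)].copy(),
            self.feature_kind,
        )


@dataclass(frozen=True)
class ReciprocalEvent:
    """One reciprocal isoform pair: a cassette exon with the junctions
    supporting its inclusion and the junction supporting its skipping."""

    event_id: str
    gene_id: str
    inclusion_junctions: tuple[str, ...]
    exclusion_junctions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.inclusion_junctions or not self.exclusion_junctions:
            raise ValidationError(
                f"{self.event_id}: inclusion and exclusion junction sets must be non-empty"
            )
        overlap = set(self.inclusion_junctions) & set(self.exclusion_junctions)
        if overlap:
            raise ValidationError(
                f"{self.event_id}: junctions in both inclusion and exclusion sets: {sorted(overlap)}"
            )


@dataclass
class ReciprocalPairCatalog:
    """Catalog of reciprocal isoform pairs, keyed by event id."""

    events: list[ReciprocalEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ev in self.events:
            if ev.event_id in seen:
                raise ValidationError(f"duplicate event id in catalog: {ev.event_id}")
            seen.add(ev.event_id)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_id(self, event_id: str) -> ReciprocalEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)


@dataclass
class ExpressionMatrix:
    """Real-valued expression, features x samples, on a flagged scale.

    ``scale`` is ``"rpkm"`` or ``"log2"``; a log2 matrix remembers the
    offset used so the transform is invertible.
    """

    values: pd.DataFrame
    scale: str
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2"):
            raise ValidationError(f"unknown expression scale {self.scale!r}")
        if self.scale == "log2" and self.offset is None:
            raise ValidationError("log2 expression must record its offset")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate feature id in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), self.scale, self.offset)


def feature_gene_map(
    models: Iterable[GeneModel], kinds: Sequence[str] = ("exon", "junction")
) -> dict[str, str]:
    """Map exon/junction feature ids to their gene id.

    Junctions shared between transcripts of one gene map once; a junction
    claimed by two different genes is rejected.
    """
    mapping: dict[str, str] = {}
    for model in models:
        ids: list[str] = []
        if "exon" in kinds:
            ids.extend(model.exon_ids())
        if "junction" in kinds:
            ids.extend(model.junction_ids())
        for fid in ids:
            prev = mapping.get(fid)
            if prev is not None and prev != model.gene_id:
                raise ValidationError(
                    f"feature {fid} assigned to two genes: {prev}, {model.gene_id}"
                )
            mapping[fid] = model.gene_id
    return mapping


def transcript_lengths(models: Iterable[GeneModel]) -> pd.Series:
    """Exon-model length per transcript id."""
    data = {m.transcript_id: m.exon_model_length for m in models}
    return pd.Series(data, dtype=np.int64)
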