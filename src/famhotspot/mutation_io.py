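"""Readers, writers and filters for somatic mutation tables and protein families.

The mutation dialect is a tab-separated derivative of a MAF file: one row per
somatic mutation, annotated with gene symbol, amino-acid change (``G12D`` style,
optionally ``p.``-prefixed), sample barcode, tumor type and mutation class.
Protein families are plain FASTA plus an optional domain-annotation TSV that
maps gene symbols to Pfam-style domain spans.

All protein coordinates in the public interface are 1-based inclusive.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MutationClass",
    "DomainSpan",
    "ProteinRecord",
    "MutationRecord",
    "ParseDiagnostics",
    "AAChangeError",
    "ConfigError",
    "DataError",
    "DEFAULT_DIALECT",
    "DEFAULT_CLASS_MAP",
    "parse_aa_change",
    "read_mutations",
    "write_mutations",
    "filter_mutations",
    "read_family",
    "validate_against_sequences",
]

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
AA_SYMBOLS = AA_LETTERS | {"X", "*"}


class ConfigError(ValueError):
    """Bad configuration: missing column, unknown mode, malformed mapping."""


class DataError(ValueError):
    """Input data violates an invariant that cannot be skipped over."""


class AAChangeError(ValueError):
    """Amino-acid-change string not parseable as a single-residue substitution."""


class MutationClass(str, Enum):
    MISSENSE = "missense"
    TRUNCATING = "truncating"
    SILENT = "silent"


#: raw MAF-style class strings -> the three-way class used for filtering.
#: Missense-type = protein-altering without frame disruption or stop gain;
#: truncating = nonsense / frameshift / splice; silent = synonymous.
DEFAULT_CLASS_MAP: dict[str, MutationClass] = {
    "Missense_Mutation": MutationClass.MISSENSE,
    "missense": MutationClass.MISSENSE,
    "In_Frame_Del": MutationClass.MISSENSE,
    "In_Frame_Ins": MutationClass.MISSENSE,
    "Nonsense_Mutation": MutationClass.TRUNCATING,
    "Nonstop_Mutation": MutationClass.TRUNCATING,
    "Frame_Shift_Del": MutationClass.TRUNCATING,
    "Frame_Shift_Ins": MutationClass.TRUNCATING,
    "Splice_Site": MutationClass.TRUNCATING,
    "truncating": MutationClass.TRUNCATING,
    "Silent": MutationClass.SILENT,
    "silent": MutationClass.SILENT,
    "Synonymous": MutationClass.SILENT,
}

#: logical field -> default column name in the tab-separated mutation file.
DEFAULT_DIALECT: dict[str, str] = {
    "gene_symbol": "Hugo_Symbol",
    "aa_change": "Amino_Acid_Change",
    "sample_id": "Tumor_Sample_Barcode",
    "tumor_type": "Tumor_Type",
    "mutation_class": "Mutation_Type",
}


@dataclass(frozen=True)
class DomainSpan:
    """One Pfam-style domain occurrence on a protein, 1-based inclusive."""

    family_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"invalid domain span {self.family_id}: start={self.start} end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """One family member: identifiers, amino-acid sequence, optional domains.

    ``offset`` is the 1-based position on the full-length protein of the first
    residue of ``sequence``; it is 1 for full-length records and moves when a
    record is trimmed to a domain, so mutation coordinates (always given on the
    full protein) stay translatable.
    """

    gene_symbol: str
    protein_id: str
    sequence: str
    domains: list[DomainSpan] = field(default_factory=list)
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"{self.gene_symbol}: empty sequence")
        bad = set(self.sequence) - AA_LETTERS - {"X"}
        if bad:
            raise DataError(
                f"{self.gene_symbol}: invalid residue symbols {sorted(bad)!r}"
            )
        end = self.offset + len(self.sequence) - 1
        for d in self.domains:
            if self.offset == 1 and d.end > len(self.sequence):
                raise DataError(
                    f"{self.gene_symbol}: domain {d.family_id} [{d.start},{d.end}] "
                    f"exceeds sequence length {len(self.sequence)}"
                )
            if d.start > end:
                raise DataError(
                    f"{self.gene_symbol}: domain {d.family_id} outside record span"
                )

    def trimmed(self, span: DomainSpan) -> "ProteinRecord":
        """Record restricted to ``span`` (inclusive); offset records the cut."""
        if self.offset != 1:
            raise DataError(f"{self.gene_symbol}: already trimmed")
        sub = self.sequence[span.start - 1 : span.end]
        return ProteinRecord(
            gene_symbol=self.gene_symbol,
            protein_id=self.protein_id,
            sequence=sub,
            domains=[span],
            offset=span.start,
        )


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-residue substitution on a protein."""

    gene_symbol: str
    sample_id: str
    tumor_type: str
    mutation_class: MutationClass
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"{self.gene_symbol}: position {self.position} < 1")
        if self.ref_aa not in AA_SYMBOLS or self.alt_aa not in AA_SYMBOLS:
            raise DataError(
                f"{self.gene_symbol}: invalid residue {self.ref_aa}>{self.alt_aa}"
            )

    @property
    def aa_change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class ParseDiagnostics:
    """Bookkeeping for rows that did not survive parsing or validation."""

    n_rows: int = 0
    n_parsed: int = 0
    n_bad_change: int = 0
    n_unknown_class: int = 0
    skipped_changes: list[str] = field(default_factory=list)
    dropped_by_gene: Counter = field(default_factory=Counter)

    @property
    def n_skipped(self) -> int:
        return self.n_bad_change + self.n_unknown_class


_AA_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*])$")


def parse_aa_change(change: str) -> tuple[str, int, str]:
    """Split ``"Q61H"`` (optionally ``"p.Q61H"``) into (ref, position, alt).

    Only single-residue substitutions are parseable; in-frame deletions such as
    ``"K601del"`` raise :class:`AAChangeError` so the caller can skip and count
    them — hotspot counting only needs point substitutions.
    """
    m = _AA_CHANGE_RE.match(change.strip()) if isinstance(change, str) else None
    if m is None:
        raise AAChangeError(f"not a single-residue substitution: {change!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AA_SYMBOLS - {"*"} or alt not in AA_SYMBOLS:
        raise AAChangeError(f"invalid residue symbol in {change!r}")
    if pos < 1:
        raise AAChangeError(f"position must be >= 1 in {change!r}")
    return ref, pos, alt


def read_mutations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    class_map: Mapping[str, MutationClass] | None = None,
) -> tuple[list[MutationRecord], ParseDiagnostics]:
    """Read the tab-separated mutation dialect into records.

    Rows whose amino-acid change is not a single-residue substitution, or whose
    mutation-class string is not in ``class_map``, are skipped and counted in
    the returned diagnostics. A missing required column is a fatal
    :class:`ConfigError`; an empty file (header only) yields an empty list with
    a warning.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    cmap = dict(DEFAULT_CLASS_MAP) if class_map is None else dict(class_map)

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for logical, name in cols.items():
        if name not in df.columns:
            raise ConfigError(
                f"mutation file {path} is missing required column {name!r} "
                f"(mapped from field {logical!r})"
            )
    diag = ParseDiagnostics(n_rows=len(df))
    if len(df) == 0:
        warnings.warn(f"mutation file {path} contains no data rows")
        return [], diag

    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        change = r[cols["aa_change"]]
        raw_class = r[cols["mutation_class"]]
        if raw_class not in cmap:
            diag.n_unknown_class += 1
            continue
        try:
            ref, pos, alt = parse_aa_change(change)
        except AAChangeError:
            diag.n_bad_change += 1
            if len(diag.skipped_changes) < 20:
                diag.skipped_changes.append(str(change))
            continue
        records.append(
            MutationRecord(
                gene_symbol=r[cols["gene_symbol"]],
                sample_id=r[cols["sample_id"]],
                tumor_type=r[cols["tumor_type"]],
                mutation_class=cmap[raw_class],
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
            )
        )
    diag.n_parsed = len(records)
    return records, diag


_CLASS_TO_RAW = {
    MutationClass.MISSENSE: "Missense_Mutation",
    MutationClass.TRUNCATING: "Nonsense_Mutation",
    MutationClass.SILENT: "Silent",
}


def write_mutations(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records back to the tab-separated dialect (inverse of read)."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = [
        {
            cols["gene_symbol"]: r.gene_symbol,
            cols["aa_change"]: r.aa_change,
            cols["sample_id"]: r.sample_id,
            cols["tumor_type"]: r.tumor_type,
            cols["mutation_class"]: _CLASS_TO_RAW[r.mutation_class],
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=[cols[k] for k in DEFAULT_DIALECT])
    df.to_csv(path, sep="\t", index=False)


_FILTER_MODES = {
    "missense_only": {MutationClass.MISSENSE},
    "include_truncating": {MutationClass.MISSENSE, MutationClass.TRUNCATING},
    "silent_only": {MutationClass.SILENT},
}


def filter_mutations(
    records: Sequence[MutationRecord], mode: str = "missense_only"
) -> list[MutationRecord]:
    """Keep records of the classes selected by ``mode``, order preserved.

    ``missense_only`` (default) retains protein-altering, frame-preserving
    substitutions; ``include_truncating`` adds nonsense/frameshift/splice
    events; ``silent_only`` retains synonymous changes (the negative-control
    workflow).
    """
    try:
        keep = _FILTER_MODES[mode]
    except KeyError:
        raise ConfigError(
            f"unknown filter mode {mode!r}; expected one of {sorted(_FILTER_MODES)}"
        ) from None
    return [r for r in records if r.mutation_class in keep]


def read_family(
    fasta_path: str | Path,
    domain_table_path: str | Path | None = None,
    family_filter: str | None = None,
) -> list[ProteinRecord]:
    """Load a protein family from FASTA, optionally with domain annotations.

    The domain table is a TSV with header columns ``gene_symbol``,
    ``family_id``, ``start``, ``end`` (1-based inclusive). When
    ``family_filter`` is given, records are trimmed to their span for that
    family and records without such a span are dropped. Domain rows citing a
    gene absent from the FASTA produce a warning and are ignored; a duplicate
    gene symbol in the FASTA is fatal.
    """
    records: dict[str, ProteinRecord] = {}
    for seq in SeqIO.parse(str(fasta_path), "fasta"):
        gene = seq.id.split("|")[0]
        protein_id = seq.id.split("|")[1] if "|" in seq.id else seq.id
        if gene in records:
            raise DataError(f"duplicate gene symbol {gene!r} in {fasta_path}")
        records[gene] = ProteinRecord(gene, protein_id, str(seq.seq).upper())

    if domain_table_path is not None:
        table = pd.read_csv(domain_table_path, sep="\t", dtype=str)
        required = {"gene_symbol", "family_id", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(
                f"domain table {domain_table_path} missing columns {sorted(missing)}"
            )
        for row in table.itertuples(index=False):
            if row.gene_symbol not in records:
                warnings.warn(
                    f"domain table row for unknown gene {row.gene_symbol!r} ignored"
                )
                continue
            records[row.gene_symbol].domains.append(
                DomainSpan(row.family_id, int(row.start), int(row.end))
            )

    out = list(records.values())
    if family_filter is not None:
        trimmed = []
        for rec in out:
            spans = [d for d in rec.domains if d.family_id == family_filter]
            for span in spans:
                trimmed.append(rec.trimmed(span))
                break  # first occurrence of the domain per protein
        out = trimmed
    return out


def validate_against_sequences(
    records: Sequence[MutationRecord],
    family: Sequence[ProteinRecord],
) -> tuple[list[MutationRecord], ParseDiagnostics]:
    """Drop mutations that contradict the family sequences.

    A mutation is dropped (and counted per gene) when its position exceeds the
    protein length or its reference residue disagrees with the sequence —
    transcript-isoform mismatches are the usual cause and must not corrupt the
    pooled profile. Mutations on genes not in the family are kept: pooling
    handles them with its own diagnostics.
    """
    by_gene = {r.gene_symbol: r for r in family}
    diag = ParseDiagnostics(n_rows=len(records))
    kept: list[MutationRecord] = []
    for m in records:
        rec = by_gene.get(m.gene_symbol)
        if rec is not None:
            idx = m.position - rec.offset  # 0-based within the stored fragment
            if idx < 0 or idx >= len(rec.sequence):
                if rec.offset == 1:  # genuinely beyond the protein
                    diag.dropped_by_gene[m.gene_symbol] += 1
                    continue
                kept.append(m)  # outside the trimmed fragment: pooling decides
                continue
            if rec.sequence[idx] != m.ref_aa and m.ref_aa != "X":
                diag.dropped_by_gene[m.gene_symbol] += 1
                continue
        kept.append(m)
    diag.n_parsed = len(kept)
    return kept, diag
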