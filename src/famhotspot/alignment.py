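"""Multiple alignment of family members and mutation pooling onto the consensus.

The consensus alignment is the shared coordinate system of the whole method:
every member's mutations are remapped onto consensus columns so that rarely
mutated members contribute to the same pooled per-column counts as heavily
mutated ones. This module builds or ingests the alignment, keeps bidirectional
maps between original residue coordinates and consensus columns, and pools
mutation records into a per-column count profile with full provenance for
reverse mapping.

Backends:

``builtin``
    Deterministic center-star progressive alignment (BLOSUM62, affine gaps),
    adequate for tests and small families. Pairwise steps use Biopython's
    ``PairwiseAligner``; the star merge follows "once a gap, always a gap".
    It is not a Clustal Omega reimplementation, and its use is logged.
``external_aligner``
    Shells out to a clustal-omega-compatible executable.
``prealigned``
    Ingests an aligned FASTA whose degapped rows must match the input
    sequences exactly.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .mutation_io import DataError, MutationRecord, ProteinRecord

__all__ = [
    "MultipleAlignment",
    "ConsensusProfile",
    "MutationProfile",
    "PoolDiagnostics",
    "GAP",
    "align_family",
    "build_consensus",
    "map_to_consensus",
    "reverse_map",
    "pool_mutations",
    "subset_members",
    "read_aligned_fasta",
    "write_aligned_fasta",
]

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class MultipleAlignment:
    """Gapped rows over a common column frame, plus coordinate maps.

    ``offsets[m]`` is the 1-based position on member *m*'s full protein of the
    first residue of its aligned fragment (1 unless the family was trimmed to
    a domain), so all public mutation coordinates can stay full-protein.
    """

    member_ids: list[str]
    rows: list[str]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise DataError("alignment needs at least one row")
        if len(self.member_ids) != len(self.rows):
            raise DataError("member_ids and rows differ in length")
        k = len(self.rows[0])
        if any(len(r) != k for r in self.rows):
            raise DataError("alignment rows have unequal lengths")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise DataError("duplicate member ids in alignment")
        for m in self.member_ids:
            self.offsets.setdefault(m, 1)
        self._index = {m: i for i, m in enumerate(self.member_ids)}
        # per member: 0-based column of each residue (residue order)
        self._pos_to_col: dict[str, np.ndarray] = {}
        for m, row in zip(self.member_ids, self.rows):
            self._pos_to_col[m] = np.flatnonzero(np.frombuffer(row.encode(), np.uint8) != ord(GAP))

    @property
    def K(self) -> int:
        """Alignment (consensus) length."""
        return len(self.rows[0])

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def row(self, member: str) -> str:
        try:
            return self.rows[self._index[member]]
        except KeyError:
            raise DataError(f"unknown member {member!r}") from None

    def degapped(self, member: str) -> str:
        return self.row(member).replace(GAP, "")


@dataclass
class ConsensusProfile:
    """Per-column consensus residue, non-gap coverage and Trident score.

    ``coverage`` carries the weights of the bootstrap null sampler: the
    probability of a random mutation landing on a column is proportional to
    the number of residues aligned there.
    """

    consensus: str
    coverage: np.ndarray
    trident: np.ndarray

    @property
    def K(self) -> int:
        return len(self.consensus)


@dataclass
class PoolDiagnostics:
    unknown_gene: int = 0
    out_of_fragment: int = 0

    @property
    def n_excluded(self) -> int:
        return self.unknown_gene + self.out_of_fragment


@dataclass
class MutationProfile:
    """Pooled per-column mutation counts with per-mutation provenance."""

    counts: np.ndarray
    provenance: list[list[tuple[str, int, str, str]]]  # (gene, pos, sample, tumor)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def K(self) -> int:
        return len(self.counts)


_aligner: PairwiseAligner | None = None


def _pairwise_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _aligner = a
    return _aligner


def _pairwise(a: str, b: str) -> tuple[str, str]:
    aln = _pairwise_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _center_star(ids: Sequence[str], seqs: Sequence[str]) -> list[str]:
    """Progressive star alignment around the member closest to all others."""
    n = len(seqs)
    if n == 1:
        return [seqs[0]]
    aligner = _pairwise_aligner()
    scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            scores[i] += s
            scores[j] += s
    center = int(np.argmax(scores))  # ties: first index, deterministic

    master = seqs[center]  # center with accumulated gaps
    aligned: list[list[str]] = []  # non-center rows, in master frame
    order = [i for i in range(n) if i != center]
    for idx in order:
        c_aln, s_aln = _pairwise(master.replace(GAP, ""), seqs[idx])
        # merge master (old gaps) with c_aln (new gaps) over the same center
        new_master: list[str] = []
        new_row: list[str] = []
        grow: list[tuple[int, int]] = []  # (old master col span consumed, gaps inserted)
        i = j = 0
        inserts: list[int] = []  # positions in old-master frame where a column is inserted
        while i < len(master) or j < len(c_aln):
            a = master[i] if i < len(master) else None
            b = c_aln[j] if j < len(c_aln) else None
            if a == GAP:
                new_master.append(GAP)
                new_row.append(GAP)
                i += 1
            elif b == GAP:
                new_master.append(GAP)
                new_row.append(s_aln[j])
                inserts.append(i)
                j += 1
            else:
                # both are the same center residue
                new_master.append(a)  # type: ignore[arg-type]
                new_row.append(s_aln[j])
                i += 1
                j += 1
        del grow
        if inserts:
            # propagate the new gap columns into previously merged rows
            for r in range(len(aligned)):
                old = aligned[r]
                out: list[str] = []
                it = iter(sorted(inserts))
                nxt = next(it, None)
                for pos in range(len(master) + 1):
                    while nxt is not None and nxt == pos:
                        out.append(GAP)
                        nxt = next(it, None)
                    if pos < len(master):
                        out.append(old[pos])
                aligned[r] = out
        master = "".join(new_master)
        aligned.append(new_row)

    rows_by_index: dict[int, str] = {center: master}
    for idx, row in zip(order, aligned):
        rows_by_index[idx] = "".join(row)
    return [rows_by_index[i] for i in range(n)]


def align_family(
    records: Sequence[ProteinRecord],
    backend: str = "builtin",
    aligned_fasta: str | Path | None = None,
    executable: str = "clustalo",
) -> MultipleAlignment:
    """Produce a MultipleAlignment of the family with the chosen backend."""
    if not records:
        raise DataError("align_family needs at least one record")
    ids = [r.gene_symbol for r in records]
    seqs = [r.sequence for r in records]
    offsets = {r.gene_symbol: r.offset for r in records}

    if backend == "builtin":
        if len(records) > 1:
            logger.info(
                "builtin center-star aligner used for %d members "
                "(deterministic; not a Clustal Omega reimplementation)",
                len(records),
            )
        rows = _center_star(ids, seqs)
        aln = MultipleAlignment(ids, rows, offsets)
    elif backend == "prealigned":
        if aligned_fasta is None:
            raise DataError("prealigned backend needs aligned_fasta")
        aln = read_aligned_fasta(aligned_fasta, offsets=offsets)
        aln_ids = set(aln.member_ids)
        if aln_ids != set(ids):
            raise DataError(
                f"prealigned members {sorted(aln_ids)} do not match records {sorted(ids)}"
            )
    elif backend == "external_aligner":
        if shutil.which(executable) is None:
            raise DataError(
                f"external aligner {executable!r} not found on PATH; "
                "use backend='prealigned' with an aligned FASTA, or backend='builtin'"
            )
        with tempfile.TemporaryDirectory() as tmp:
            fin = Path(tmp) / "in.fasta"
            fout = Path(tmp) / "out.fasta"
            fin.write_text("".join(f">{i}\n{s}\n" for i, s in zip(ids, seqs)))
            subprocess.run(
                [executable, "-i", str(fin), "-o", str(fout), "--outfmt", "fasta", "--force"],
                check=True,
                capture_output=True,
            )
            aln = read_aligned_fasta(fout, offsets=offsets)
    else:
        raise DataError(f"unknown alignment backend {backend!r}")

    for rec in records:
        if aln.degapped(rec.gene_symbol) != rec.sequence:
            raise DataError(
                f"alignment row of {rec.gene_symbol} does not reproduce its sequence"
            )
    return aln


def build_consensus(aln: MultipleAlignment) -> ConsensusProfile:
    """Most-represented residue, non-gap coverage and Trident per column.

    Ties among equally frequent residues break to the alphabetically first.
    Gaps never become consensus while any residue is present; an all-gap
    column (possible after subsetting members) gets consensus ``-`` and
    coverage 0.
    """
    from .conservation import trident_profile  # late import: no cycle at load

    K = aln.K
    consensus = []
    coverage = np.zeros(K, dtype=int)
    for c in range(K):
        col = [row[c] for row in aln.rows]
        residues = [x for x in col if x != GAP]
        coverage[c] = len(residues)
        if not residues:
            consensus.append(GAP)
            continue
        counts = Counter(residues)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        # max by count, then lexicographically smallest residue
        consensus.append(best[0])
    trident = trident_profile(aln)
    return ConsensusProfile("".join(consensus), coverage, trident)


def map_to_consensus(aln: MultipleAlignment, member: str, position: int) -> int:
    """Consensus column (1-based) holding ``member``'s residue at ``position``.

    ``position`` is on the full protein; the member's fragment offset is
    applied internally.
    """
    cols = aln._pos_to_col.get(member)
    if cols is None:
        raise DataError(f"unknown member {member!r}")
    idx = position - aln.offsets[member]
    if idx < 0 or idx >= len(cols):
        raise DataError(
            f"position {position} of {member} outside the aligned fragment "
            f"[{aln.offsets[member]}, {aln.offsets[member] + len(cols) - 1}]"
        )
    return int(cols[idx]) + 1


def reverse_map(aln: MultipleAlignment, column: int) -> list[tuple[str, int]]:
    """Members with a residue in ``column`` and its original protein position."""
    if not (1 <= column <= aln.K):
        raise DataError(f"column {column} out of range 1..{aln.K}")
    out: list[tuple[str, int]] = []
    c = column - 1
    for m, row in zip(aln.member_ids, aln.rows):
        if row[c] != GAP:
            pos_in_frag = row[: c + 1].count(GAP)
            pos_in_frag = c + 1 - pos_in_frag  # 1-based residue index in fragment
            out.append((m, pos_in_frag + aln.offsets[m] - 1))
    return out


def pool_mutations(
    aln: MultipleAlignment,
    muts: Sequence[MutationRecord],
    member_offset: Mapping[str, int] | None = None,
) -> tuple[MutationProfile, PoolDiagnostics]:
    """Pool class-filtered mutations onto consensus columns.

    Mutations on genes absent from the alignment, or falling outside a
    member's aligned fragment, are excluded and counted in the diagnostics;
    everything else increments its column count and is recorded in the
    per-column provenance for later reverse mapping.
    """
    offsets = dict(aln.offsets)
    if member_offset:
        offsets.update(member_offset)
    counts = np.zeros(aln.K, dtype=int)
    provenance: list[list[tuple[str, int, str, str]]] = [[] for _ in range(aln.K)]
    diag = PoolDiagnostics()
    members = set(aln.member_ids)
    for m in muts:
        if m.gene_symbol not in members:
            diag.unknown_gene += 1
            continue
        cols = aln._pos_to_col[m.gene_symbol]
        idx = m.position - offsets[m.gene_symbol]
        if idx < 0 or idx >= len(cols):
            diag.out_of_fragment += 1
            continue
        c = int(cols[idx])
        counts[c] += 1
        provenance[c].append((m.gene_symbol, m.position, m.sample_id, m.tumor_type))
    return MutationProfile(counts, provenance), diag


def subset_members(aln: MultipleAlignment, keep: Sequence[str]) -> MultipleAlignment:
    """Restrict rows to ``keep`` without re-compacting columns.

    K and all column indices are unchanged, so hotspot positions from the
    subset remain directly comparable with the full-family analysis.
    """
    keep_set = set(keep)
    unknown = keep_set - set(aln.member_ids)
    if unknown:
        raise DataError(f"unknown members in subset: {sorted(unknown)}")
    ids = [m for m in aln.member_ids if m in keep_set]
    rows = [r for m, r in zip(aln.member_ids, aln.rows) if m in keep_set]
    return MultipleAlignment(ids, rows, {m: aln.offsets[m] for m in ids})


def read_aligned_fasta(
    path: str | Path, offsets: Mapping[str, int] | None = None
) -> MultipleAlignment:
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id.split("|")[0])
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(ids, rows, dict(offsets) if offsets else {})


def write_aligned_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, row in zip(aln.member_ids, aln.rows):
            fh.write(f">{m}\n{row}\n")


def consensus_table(aln: MultipleAlignment, profile: ConsensusProfile):
    """Consensus/coverage/Trident as a DataFrame (column is 1-based)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "column": np.arange(1, profile.K + 1),
            "consensus_aa": list(profile.consensus),
            "coverage": profile.coverage,
            "trident": profile.trident,
        }
    )
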