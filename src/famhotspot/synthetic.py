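"""Synthetic protein families and mutation cohorts with known ground truth.

The generator plays the role of the external annotation/mutation databases:
it emits a family of homologous sequences at controllable divergence together
with the true alignment, and a per-sample cohort of mutation records with
planted hotspot columns, uniform background mutations, tumor-type labels and
optional forced mutual exclusivity — so every statistical claim of the
package can be tested against a planted truth without any download.

Sequence evolution is deliberately simple: an ancestral random sequence,
independent per-member substitutions, and deletions relative to the ancestor
(no insertions), which keeps the true alignment in ancestral coordinates.
Hotspot planting happens in consensus-column space, not per-gene space, so
the family-level phenomenon — a column rarely mutated in any single member
but recurrently mutated across the family — is directly simulable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, MultipleAlignment, map_to_consensus
from .mutation_io import DataError, MutationClass, MutationRecord, ProteinRecord

__all__ = [
    "FamilySpec",
    "CohortSpec",
    "generate_family",
    "generate_cohort",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """Homologous family parameters.

    ``substitution_rate`` is the per-site probability that a member differs
    from the ancestor; ``indel_rate`` the per-site probability of a deletion
    (gap in the true alignment). Defaults emulate a moderately diverged
    Pfam-style domain family.
    """

    n_members: int = 10
    length: int = 200
    substitution_rate: float = 0.15
    indel_rate: float = 0.03
    gene_prefix: str = "GENE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise DataError("n_members must be >= 1")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Mutation cohort parameters.

    ``background_rate`` is the expected number of background mutations per
    sample (placed uniformly over all (member, residue) pairs);
    ``hotspot_columns`` lists (consensus column, fraction of all mutations)
    pairs; fractions must sum to <= 1. ``total_mutations`` may pin the cohort
    size explicitly — required when background_rate = 0 — otherwise the total
    is derived so that the background share matches its Poisson draw.
    ``exclusivity_pairs`` are gene pairs forced never to be co-mutated in the
    same sample (enforced by rejection). ``tumor_types`` maps labels to
    sampling probabilities.
    """

    n_samples: int = 50
    background_rate: float = 1.0
    hotspot_columns: tuple[tuple[int, float], ...] = ()
    exclusivity_pairs: tuple[tuple[str, str], ...] = ()
    tumor_types: tuple[tuple[str, float], ...] = (("PANCAN", 1.0),)
    mutation_class: MutationClass = MutationClass.MISSENSE
    total_mutations: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        frac = sum(f for _, f in self.hotspot_columns)
        if frac > 1.0 + 1e-9:
            raise DataError("hotspot fractions sum to > 1")
        if self.background_rate < 0:
            raise DataError("background_rate must be >= 0")
        if self.n_samples < 1:
            raise DataError("n_samples must be >= 1")


def generate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], MultipleAlignment]:
    """Ancestral sequence mutated independently per member, plus true alignment.

    The returned alignment is exact by construction (ancestral coordinates
    with gaps at deleted sites), enabling aligner-independent tests.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AA20))
    ancestor = rng.choice(aa, size=spec.length)
    ids: list[str] = []
    rows: list[str] = []
    records: list[ProteinRecord] = []
    for i in range(spec.n_members):
        gene = f"{spec.gene_prefix}{i + 1:03d}"
        seq = ancestor.copy()
        sub_mask = rng.random(spec.length) < spec.substitution_rate
        for j in np.flatnonzero(sub_mask):
            choices = [x for x in AA20 if x != seq[j]]
            seq[j] = choices[rng.integers(len(choices))]
        del_mask = rng.random(spec.length) < spec.indel_rate
        if del_mask.all():  # keep at least one residue
            del_mask[rng.integers(spec.length)] = False
        row = "".join(GAP if d else s for s, d in zip(seq, del_mask))
        ids.append(gene)
        rows.append(row)
        records.append(ProteinRecord(gene, f"P{i + 1:05d}", row.replace(GAP, "")))
    aln = MultipleAlignment(ids, rows)
    return records, aln


def _column_residents(aln: MultipleAlignment, column: int) -> list[tuple[str, int]]:
    """(member, protein position) pairs with a residue in the column."""
    from .alignment import reverse_map

    return reverse_map(aln, column)


def generate_cohort(
    spec: CohortSpec,
    family: Sequence[ProteinRecord],
    true_aln: MultipleAlignment,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Mutation records with planted hotspots plus a ground-truth table.

    A fraction f_h of all mutations lands on residues mapping to hotspot
    column h (member chosen coverage-weighted among members with a residue
    there); the remainder is uniform over all (member, residue) pairs. Every
    record carries a sample and tumor-type label; exclusivity pairs are
    honored by resampling the sample label. The ground-truth table lists each
    mutation with its true consensus column and the planted hotspot (or -1
    for background).
    """
    rng = np.random.default_rng(spec.seed)
    by_gene = {r.gene_symbol: r for r in family}

    residents: dict[int, list[tuple[str, int]]] = {}
    for col, frac in spec.hotspot_columns:
        res = _column_residents(true_aln, col)
        if not res:
            raise DataError(f"hotspot column {col} has zero coverage")
        residents[col] = res

    frac_sum = sum(f for _, f in spec.hotspot_columns)
    if spec.total_mutations is not None:
        n_total = int(spec.total_mutations)
    else:
        n_bg = int(rng.poisson(spec.background_rate * spec.n_samples))
        if frac_sum >= 1.0 - 1e-9:
            raise DataError(
                "hotspot fractions sum to 1: give total_mutations explicitly"
            )
        n_total = int(round(n_bg / (1.0 - frac_sum)))
    n_hot = {col: int(round(f * n_total)) for col, f in spec.hotspot_columns}
    n_bg = max(0, n_total - sum(n_hot.values()))

    all_sites = [
        (r.gene_symbol, pos)
        for r in family
        for pos in range(r.offset, r.offset + len(r.sequence))
    ]
    tumor_labels = [t for t, _ in spec.tumor_types]
    tumor_probs = np.array([p for _, p in spec.tumor_types], dtype=float)
    tumor_probs = tumor_probs / tumor_probs.sum()
    samples = [f"SAMPLE{i + 1:04d}" for i in range(spec.n_samples)]
    sample_tumor = {
        s: tumor_labels[rng.choice(len(tumor_labels), p=tumor_probs)] for s in samples
    }
    excl = {frozenset(p) for p in spec.exclusivity_pairs}
    genes_in_sample: dict[str, set[str]] = {s: set() for s in samples}

    def pick_sample(gene: str) -> str:
        for _ in range(1000):
            s = samples[rng.integers(len(samples))]
            ok = True
            for other in genes_in_sample[s]:
                if frozenset((gene, other)) in excl:
                    ok = False
                    break
            if ok:
                genes_in_sample[s].add(gene)
                return s
        raise DataError(
            f"could not honor exclusivity constraints for {gene}; constraints infeasible"
        )

    records: list[MutationRecord] = []
    truth_rows: list[dict] = []

    def emit(gene: str, pos: int, planted: int) -> None:
        rec = by_gene[gene]
        ref = rec.sequence[pos - rec.offset]
        if spec.mutation_class is MutationClass.SILENT:
            alt = ref  # protein-neutral change
        else:
            alts = [x for x in AA20 if x != ref]
            alt = alts[rng.integers(len(alts))]
        sample = pick_sample(gene)
        records.append(
            MutationRecord(
                gene_symbol=gene,
                sample_id=sample,
                tumor_type=sample_tumor[sample],
                mutation_class=spec.mutation_class,
                ref_aa=ref,
                position=pos,
                alt_aa=alt,
            )
        )
        truth_rows.append(
            {
                "gene_symbol": gene,
                "position": pos,
                "sample_id": sample,
                "tumor_type": sample_tumor[sample],
                "column": map_to_consensus(true_aln, gene, pos),
                "planted_hotspot": planted,
            }
        )

    for col, n in n_hot.items():
        res = residents[col]
        for _ in range(n):
            gene, pos = res[rng.integers(len(res))]
            emit(gene, pos, planted=col)
    for _ in range(n_bg):
        gene, pos = all_sites[rng.integers(len(all_sites))]
        emit(gene, pos, planted=-1)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_symbol",
            "position",
            "sample_id",
            "tumor_type",
            "column",
            "planted_hotspot",
        ],
    )
    return records, truth
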