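"""Column conservation (Trident) and pairwise sequence homogeneity (k-tuple).

The Trident score gates which consensus columns enter multiple-testing
correction: mutations on unconserved columns are not comparable across family
members, so their p-values are reported but never corrected. The k-tuple
similarity check is the safety net against families contaminated with a
dissimilar sequence, which would invalidate the whole alignment-based
analysis: it warns, and the analysis proceeds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import GAP, MultipleAlignment
from .mutation_io import ProteinRecord

__all__ = [
    "TridentComponents",
    "DEFAULT_EXPONENTS",
    "TRIDENT_GATE",
    "column_trident",
    "trident_profile",
    "ktuple_similarity",
    "check_homogeneity",
]

#: (alpha, beta, gamma) weights of the three Trident components, following the
#: recommendation of the original Trident (Valdar) scoring scheme.
DEFAULT_EXPONENTS: tuple[float, float, float] = (1.0, 0.5, 3.0)

#: columns must exceed this Trident score to enter BH correction.
TRIDENT_GATE = 0.1

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _blosum_distance_table() -> dict[tuple[str, str], float]:
    """BLOSUM62-derived chemical distance, 0 for identical pairs, 1 at the
    most dissimilar pair.

    Similarity is first normalized Karlin-style, s(a,b)/sqrt(s(a,a)s(b,b)),
    so every identical pair sits at 1 regardless of its diagonal score; the
    distance 1 - s_norm is then rescaled by its maximum over the 20 canonical
    residues.
    """
    m = substitution_matrices.load("BLOSUM62")
    raw = {}
    for a, b in itertools.product(_AA20, repeat=2):
        s = m[a, b] / math.sqrt(m[a, a] * m[b, b])
        raw[(a, b)] = 1.0 - s
    dmax = max(raw.values())
    return {k: v / dmax for k, v in raw.items()}


_BLOSUM_DIST = _blosum_distance_table()


@dataclass(frozen=True)
class TridentComponents:
    """The three diversity terms and their combined conservation score.

    All fields live in [0, 1]. ``t_entropy`` is the normalized symbol entropy
    of the residues at the position (more residue types = less conserved);
    ``r_chemical`` the normalized mean pairwise BLOSUM62 distance (chemically
    distant residues = less conserved); ``g_gap`` the relative gap frequency.
    The score multiplies their complements: perfectly conserved columns score
    1, all-gap columns score 0 by convention.
    """

    t_entropy: float
    r_chemical: float
    g_gap: float
    score: float


def column_trident(
    column: Iterable[str],
    exponents: tuple[float, float, float] = DEFAULT_EXPONENTS,
) -> TridentComponents:
    """Trident conservation of one alignment column.

    ``score = (1 - t)^alpha * (1 - r)^beta * (1 - g)^gamma``. Entropy and the
    chemical term are computed on the non-gap residues; the gap term on the
    whole column. An all-gap column scores 0 with ``g_gap = 1``.
    """
    col = list(column)
    if not col:
        raise ValueError("empty column")
    alpha, beta, gamma = exponents
    height = len(col)
    residues = [x for x in col if x != GAP]
    g = 1.0 - len(residues) / height
    if not residues:
        return TridentComponents(0.0, 0.0, 1.0, 0.0)

    counts = Counter(residues)
    n = len(residues)
    if len(counts) == 1:
        t = 0.0
    else:
        h = -sum((c / n) * math.log(c / n) for c in counts.values())
        hmax = math.log(min(len(_AA20), n))
        t = min(1.0, h / hmax)

    if n == 1 or len(counts) == 1:
        r = 0.0
    else:
        total = 0.0
        npairs = 0
        items = list(counts.items())
        for i, (a, ca) in enumerate(items):
            for b, cb in items[i:]:
                d = _BLOSUM_DIST.get((a, b), 1.0)
                mult = ca * (ca - 1) // 2 if a == b else ca * cb
                total += d * mult
                npairs += mult
        r = min(1.0, total / npairs) if npairs else 0.0

    score = (1.0 - t) ** alpha * (1.0 - r) ** beta * (1.0 - g) ** gamma
    return TridentComponents(t, r, g, score)


def trident_profile(
    aln: MultipleAlignment,
    exponents: tuple[float, float, float] = DEFAULT_EXPONENTS,
) -> np.ndarray:
    """Per-column Trident scores of the whole alignment (length K)."""
    out = np.empty(aln.K)
    for c in range(aln.K):
        out[c] = column_trident((row[c] for row in aln.rows), exponents).score
    return out


def ktuple_similarity(seq_a: str, seq_b: str, k: int = 3) -> float:
    """Shared distinct k-tuples over the distinct k-tuples of the shorter
    sequence.

    Degenerate case: when either sequence is shorter than ``k`` the measure
    falls back to an exact-match indicator.
    """
    if min(len(seq_a), len(seq_b)) < k:
        return float(seq_a == seq_b)
    ta = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    tb = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    shorter = ta if len(seq_a) <= len(seq_b) else tb
    return len(ta & tb) / len(shorter)


@dataclass(frozen=True)
class HomogeneityWarning:
    gene_symbol: str
    mean_similarity: float
    threshold: float

    def __str__(self) -> str:
        return (
            f"{self.gene_symbol}: mean k-tuple similarity to the family is "
            f"{self.mean_similarity:.3f} (< {self.threshold}); this sequence may "
            "invalidate the consensus analysis"
        )


def check_homogeneity(
    records: Sequence[ProteinRecord],
    threshold: float = 0.2,
    k: int = 3,
) -> list[HomogeneityWarning]:
    """Warn about members too dissimilar from the rest of the family.

    Each member's mean k-tuple similarity to all others is compared with
    ``threshold`` (default 0.2); offenders produce a named warning. Warnings
    never stop the analysis — they are a safety net, not a filter.
    """
    if len(records) < 2:
        return []
    sims = np.zeros((len(records), len(records)))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            s = ktuple_similarity(records[i].sequence, records[j].sequence, k)
            sims[i, j] = sims[j, i] = s
    out: list[HomogeneityWarning] = []
    n = len(records)
    for i, rec in enumerate(records):
        mean_sim = sims[i].sum() / (n - 1)
        if mean_sim < threshold:
            w = HomogeneityWarning(rec.gene_symbol, float(mean_sim), threshold)
            warnings.warn(str(w))
            out.append(w)
    return out
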