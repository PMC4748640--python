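"""Mutual exclusivity / co-occurrence of mutated features across samples.

Features are either whole genes or significant consensus positions; samples
are stratified by tumor type. Each feature pair is scored with the exact
probabilistic co-occurrence model: conditioning on the two features' marginal
sample counts, the number of co-mutated samples J under random placement is
hypergeometric, and p_lt (P(J <= j_obs)) small means mutual exclusivity,
p_gt (P(J >= j_obs)) small means co-occurrence. Both tails include the
observed point mass. A 2x2 Fisher exact test is also provided for
domain-level exclusivity questions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment import MultipleAlignment, map_to_consensus
from .hotspot import HotspotResult
from .mutation_io import DataError, MutationRecord

__all__ = [
    "PresenceMatrix",
    "PairResult",
    "build_presence_matrix",
    "pair_probabilities",
    "cooccur_analysis",
    "fisher_2x2",
]


@dataclass
class PresenceMatrix:
    """Binary samples x features mutation matrix for one tumor-type stratum."""

    data: pd.DataFrame  # bool, index = sample ids, columns = feature labels
    stratum: str

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise DataError("duplicate sample or feature labels")

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class PairResult:
    """Exact co-occurrence test of one feature pair in one stratum."""

    feature_a: str
    feature_b: str
    stratum: str
    n_sites: int
    n_a: int
    n_b: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    call: str  # mutually_exclusive | co_occurring | neutral
    p_adj: float
    low_power: bool


def build_presence_matrix(
    muts: Sequence[MutationRecord],
    level: str = "gene",
    hotspots: Optional[HotspotResult] = None,
    aln: Optional[MultipleAlignment] = None,
    stratum: Optional[str] = None,
    samples: Optional[Sequence[str]] = None,
) -> PresenceMatrix:
    """Binary mutated/not matrix of samples against features.

    ``level='gene'`` uses gene symbols as features. ``level='position'``
    maps each mutation to its consensus column via the alignment and keeps
    only columns called significant in ``hotspots``; a sample mutated at
    several hotspot columns is marked present in each (presence, not counts).
    ``stratum`` restricts to one tumor type; ``samples`` optionally fixes the
    full sample roster (so unmutated samples still count as sites).
    """
    if stratum is not None:
        muts = [m for m in muts if m.tumor_type == stratum]
    label = stratum if stratum is not None else "all"
    if not muts and samples is None:
        warnings.warn(f"stratum {label!r} has no mutations; empty matrix")
        return PresenceMatrix(pd.DataFrame(dtype=bool), label)

    pairs: list[tuple[str, str]] = []  # (sample, feature)
    if level == "gene":
        for m in muts:
            pairs.append((m.sample_id, m.gene_symbol))
    elif level == "position":
        if hotspots is None or aln is None:
            raise DataError("level='position' needs hotspots and the alignment")
        sig_cols = set(hotspots.significant()["column"].astype(int))
        members = set(aln.member_ids)
        for m in muts:
            if m.gene_symbol not in members:
                continue
            try:
                col = map_to_consensus(aln, m.gene_symbol, m.position)
            except DataError:
                continue
            if col in sig_cols:
                pairs.append((m.sample_id, f"pos_{col}"))
    else:
        raise DataError(f"unknown level {level!r}")

    sample_ids = sorted(samples) if samples is not None else sorted({s for s, _ in pairs})
    features = sorted({f for _, f in pairs})
    data = pd.DataFrame(False, index=sample_ids, columns=features, dtype=bool)
    for s, f in pairs:
        if s in data.index:
            data.loc[s, f] = True
    return PresenceMatrix(data, label)


def pair_probabilities(
    n_sites: int, n_a: int, n_b: int, j_obs: int
) -> tuple[float, float, float]:
    """Exact tail probabilities of the co-occurrence count.

    With n_a and n_b mutated samples placed at random among n_sites, the
    co-mutated count J is hypergeometric:
    P(J = j) = C(n_a, j) C(n_sites - n_a, n_b - j) / C(n_sites, n_b).
    Returns (p_lt, p_gt, expected) with p_lt = P(J <= j_obs),
    p_gt = P(J >= j_obs), expected = n_a n_b / n_sites. Both tails share the
    observed point mass, so p_lt + p_gt >= 1.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0 <= n_a <= n_sites and 0 <= n_b <= n_sites):
        raise ValueError("feature counts outside [0, n_sites]")
    lo = max(0, n_a + n_b - n_sites)
    hi = min(n_a, n_b)
    if not (lo <= j_obs <= hi):
        raise ValueError(
            f"infeasible j_obs={j_obs} for n_sites={n_sites}, n_a={n_a}, n_b={n_b}"
        )
    expected = n_a * n_b / n_sites
    rv = stats.hypergeom(n_sites, n_a, n_b)
    p_lt = float(rv.cdf(j_obs))
    p_gt = float(rv.sf(j_obs - 1))
    return min(p_lt, 1.0), min(p_gt, 1.0), expected


def cooccur_analysis(
    matrix: PresenceMatrix,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> list[PairResult]:
    """Score every feature pair and call exclusivity/co-occurrence.

    Tail p-values are corrected across all pairs within the stratum
    (Benjamini–Hochberg by default; ``'none'`` and ``'bonferroni'`` are
    accepted); a pair is ``mutually_exclusive`` when its adjusted p_lt falls
    below ``alpha``, ``co_occurring`` when its adjusted p_gt does, otherwise
    ``neutral``. Pairs whose expected co-occurrence is below 1 are flagged
    ``low_power``.
    """
    feats = matrix.features
    if len(feats) < 2:
        raise DataError("pairwise analysis needs at least 2 features")
    M = matrix.data.to_numpy(dtype=bool)
    n_sites = matrix.n_samples
    raw: list[tuple[str, str, int, int, int, float, float, float]] = []
    for i, j in combinations(range(len(feats)), 2):
        a, b = M[:, i], M[:, j]
        n_a, n_b = int(a.sum()), int(b.sum())
        j_obs = int((a & b).sum())
        p_lt, p_gt, expected = pair_probabilities(n_sites, n_a, n_b, j_obs)
        raw.append((feats[i], feats[j], n_a, n_b, j_obs, expected, p_lt, p_gt))

    p_lt_all = np.array([r[6] for r in raw])
    p_gt_all = np.array([r[7] for r in raw])
    if correction == "none":
        adj_lt, adj_gt = p_lt_all, p_gt_all
    elif correction in ("fdr_bh", "bonferroni"):
        adj_lt = multipletests(p_lt_all, method=correction)[1]
        adj_gt = multipletests(p_gt_all, method=correction)[1]
    else:
        raise DataError(f"unknown correction {correction!r}")

    out: list[PairResult] = []
    for k, (fa, fb, n_a, n_b, j_obs, expected, p_lt, p_gt) in enumerate(raw):
        if adj_lt[k] < alpha:
            call = "mutually_exclusive"
            p_adj = float(adj_lt[k])
        elif adj_gt[k] < alpha:
            call = "co_occurring"
            p_adj = float(adj_gt[k])
        else:
            call = "neutral"
            p_adj = float(min(adj_lt[k], adj_gt[k]))
        out.append(
            PairResult(
                feature_a=fa,
                feature_b=fb,
                stratum=matrix.stratum,
                n_sites=n_sites,
                n_a=n_a,
                n_b=n_b,
                j_obs=j_obs,
                expected=expected,
                p_lt=p_lt,
                p_gt=p_gt,
                call=call,
                p_adj=p_adj,
                low_power=expected < 1.0,
            )
        )
    return out


def pair_results_table(results: Sequence[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio (a d)/(b c) and the conditional exact
    two-sided p-value. Degenerate cells: OR is ``inf`` when b c = 0 with
    a d > 0, and ``nan`` when both products are 0; an all-zero table is an
    error.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)
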