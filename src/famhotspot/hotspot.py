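"""Hotspot statistics: entropy, bootstrap Gamma null, per-position tests.

The pooled per-column mutation counts are tested at two levels.

Globally, the Shannon entropy of the count-frequency vector measures how
clustered the profile is (hotspots lower it). The observed entropy is compared
against entropies of bootstrap profiles drawn as multinomials with the same
total N and coverage-proportional column weights — the more gaps a column has,
the less likely a random mutation lands there — and a Gamma distribution
fitted to the bootstrap entropy distribution supplies the null. Because
clustering strictly reduces entropy, small entropy is the alternative: the
test works on the entropy deficit D = ln(min(N, K)) - H (the drop below the
maximum attainable entropy), which is non-negative and right-skewed — the
natural orientation for a Gamma — and the global p-value is the fitted
Gamma's upper tail in D, equivalently the lower tail in H.

Per position, the same bootstrap yields a per-column null for the count
n_i; a Gamma is fitted to the bootstrap counts of each column and the
upper tail at n_i gives the per-position p-value. P-values of conserved
columns (Trident score > 0.1) are Benjamini–Hochberg corrected into q-values;
unconserved columns keep their p but get no q, so nothing silently disappears.

Counts are discrete and zero-inflated while the Gamma lives on (0, inf), so a
documented continuity/fallback rule applies: columns whose bootstrap counts
are >90 % zeros use a smoothed empirical exceedance instead of a Gamma fit;
otherwise the Gamma is fitted to counts + 0.5 and evaluated at n_i - 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .alignment import (
    ConsensusProfile,
    MultipleAlignment,
    MutationProfile,
)
from .conservation import TRIDENT_GATE

__all__ = [
    "GammaParams",
    "NullModel",
    "HotspotResult",
    "NoMutationsError",
    "shannon_entropy",
    "sampling_weights",
    "simulate_null",
    "build_null",
    "fit_gamma",
    "global_pvalue",
    "position_pvalues",
    "correct_qvalues",
    "call_hotspots",
]


class NoMutationsError(ValueError):
    """The pooled profile carries no mutations; there is nothing to test."""


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale (optionally shifted) parametrization; both positive."""

    shape: float
    scale: float
    loc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(f"invalid Gamma parameters {self}")


@dataclass
class NullModel:
    """Bootstrap null of the pooled profile.

    ``boot_counts`` is the n_boot x K matrix of simulated per-column counts
    (each replicate sums to N exactly); ``entropy_null`` is the Gamma fitted
    to the replicate entropy deficits ``deficit_ref - H``, or None when the
    fit is degenerate and the empirical tail must be used. Per-column Gamma
    fits are filled lazily by :func:`position_pvalues`.
    """

    weights: np.ndarray
    N: int
    n_boot: int
    seed: int
    boot_counts: np.ndarray
    boot_entropies: np.ndarray
    entropy_null: Optional[GammaParams]
    deficit_ref: float = 0.0
    position_null: list[Optional[GammaParams]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.weights)


def _entropy_of_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n <= 0:
        raise NoMutationsError("entropy undefined for an all-zero profile")
    p = counts / n
    return float(-special.xlogy(p, p).sum())


def shannon_entropy(profile: MutationProfile | np.ndarray | Sequence[int]) -> float:
    """Natural-log Shannon entropy H = -sum (n_i/N) ln(n_i/N) of the profile.

    Zero-count positions contribute nothing; an empty profile (N = 0) raises
    :class:`NoMutationsError` because the global test is meaningless without
    mutations.
    """
    counts = profile.counts if isinstance(profile, MutationProfile) else np.asarray(profile, float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return _entropy_of_counts(np.asarray(counts, dtype=float))


def sampling_weights(profile: ConsensusProfile | np.ndarray) -> np.ndarray:
    """Coverage-proportional column weights of the bootstrap null sampler."""
    cov = profile.coverage if isinstance(profile, ConsensusProfile) else np.asarray(profile)
    cov = np.asarray(cov, dtype=float)
    total = cov.sum()
    if total <= 0:
        raise ValueError("all-zero coverage: no residues to place mutations on")
    return cov / total


def simulate_null(
    weights: np.ndarray, N: int, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """n_boot multinomial profiles of N mutations over the weighted columns."""
    weights = np.asarray(weights, dtype=float)
    if N < 1:
        raise ValueError("N must be >= 1")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be a probability vector")
    rng = np.random.default_rng(seed)
    return rng.multinomial(N, weights, size=n_boot)


def _boot_entropies(boot_counts: np.ndarray) -> np.ndarray:
    n = boot_counts.sum(axis=1, keepdims=True).astype(float)
    p = boot_counts / n
    return -special.xlogy(p, p).sum(axis=1)


def _gamma_mle(x: np.ndarray) -> GammaParams:
    """Maximum-likelihood Gamma fit, moment-matching initialization.

    Newton iteration on the profile log-likelihood in the shape parameter:
    ln(k) - digamma(k) = ln(mean) - mean(ln x); scale = mean / k.
    """
    mean = x.mean()
    s = np.log(mean) - np.log(x).mean()
    if s <= 0:  # numerically constant sample
        raise ValueError("zero-variance sample")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return GammaParams(float(k), float(mean / k))


def fit_gamma(samples: Sequence[float] | np.ndarray) -> Optional[GammaParams]:
    """Fit a Gamma to positive samples; None marks a degenerate sample.

    Zeros (and negatives) are outside the Gamma support and are dropped before
    fitting; a sample with fewer than two distinct positive values, or with
    essentially zero variance, cannot identify the parameters and returns the
    degenerate marker instead.
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    if len(x) < 2 or len(np.unique(x)) < 2:
        return None
    if x.var() < 1e-12 * max(x.mean() ** 2, 1e-300):
        return None
    try:
        return _gamma_mle(x)
    except (ValueError, FloatingPointError):
        return None


def build_null(
    weights: np.ndarray,
    N: int,
    n_boot: int = 1000,
    seed: int = 0,
    zero_entropy_fallback: float = 0.1,
) -> NullModel:
    """Simulate the bootstrap and fit the global entropy Gamma null.

    The Gamma is fitted (maximum likelihood, shifted three-parameter form) to
    the replicate entropy deficits ``ln(min(N, K)) - H``, which are
    non-negative and right-skewed. Zero-entropy replicates (all N mutations
    on one column, possible at tiny N) sit at the deficit's upper support
    bound and are excluded from the fit; when they exceed
    ``zero_entropy_fallback`` of the replicates the Gamma is abandoned and
    the empirical tail is used instead (``entropy_null = None``).
    """
    boot = simulate_null(weights, N, n_boot=n_boot, seed=seed)
    ents = _boot_entropies(boot)
    K = len(np.asarray(weights))
    deficit_ref = float(np.log(min(N, K)))
    zero_frac = np.mean(ents <= 0)
    entropy_null = None
    if zero_frac <= zero_entropy_fallback:
        deficits = deficit_ref - ents[ents > 0]
        if len(np.unique(deficits)) >= 2 and deficits.var() > 1e-14:
            try:
                shape, loc, scale = stats.gamma.fit(deficits)
                entropy_null = GammaParams(float(shape), float(scale), float(loc))
            except (ValueError, RuntimeError):
                entropy_null = None
    return NullModel(
        weights=np.asarray(weights, dtype=float),
        N=int(N),
        n_boot=int(n_boot),
        seed=int(seed),
        boot_counts=boot,
        boot_entropies=ents,
        entropy_null=entropy_null,
        deficit_ref=deficit_ref,
    )


def global_pvalue(H_obs: float, null: NullModel) -> float:
    """Lower-tail p-value of the observed profile entropy under the null.

    Clustering of mutations strictly reduces entropy, so small H is the
    alternative of interest: p = P(H_null <= H_obs), evaluated as the upper
    tail of the Gamma fitted to the entropy deficit, or as the smoothed
    empirical fraction of bootstrap entropies at or below H_obs when the fit
    was degenerate.
    """
    if null.entropy_null is not None:
        g = null.entropy_null
        return float(stats.gamma.sf(null.deficit_ref - H_obs, g.shape, loc=g.loc, scale=g.scale))
    n = len(null.boot_entropies)
    return float((1 + np.sum(null.boot_entropies <= H_obs)) / (n + 1))


def position_pvalues(
    profile: MutationProfile | np.ndarray,
    null: NullModel,
    zero_fraction_fallback: float = 0.9,
) -> np.ndarray:
    """Upper-tail per-column p-values of the observed counts.

    Per column i a Gamma is fitted to the bootstrap counts (continuity offset
    +0.5) and p_i = P(X >= n_i) is its upper tail at n_i - 0.5. Columns with
    n_i = 0 carry no evidence and get p = 1; zero-weight columns get p = 1
    with a diagnostic (such a mutation is unmappable anyway); columns whose
    bootstrap counts are more than 90 % zeros — or otherwise degenerate — use
    the smoothed empirical exceedance (1 + #{boot >= n_i}) / (n_boot + 1).
    """
    counts = profile.counts if isinstance(profile, MutationProfile) else np.asarray(profile)
    counts = np.asarray(counts)
    if len(counts) != null.K:
        raise ValueError("profile length does not match the null model")
    B = null.boot_counts
    n_boot = B.shape[0]
    K = null.K
    p = np.ones(K, dtype=float)
    fits: list[Optional[GammaParams]] = [None] * K

    zero_weight = null.weights <= 0
    if np.any(zero_weight & (counts > 0)):
        warnings.warn(
            "observed mutations on zero-weight (all-gap) columns; p set to 1"
        )
    zero_frac = np.mean(B == 0, axis=0)
    testable = (~zero_weight) & (counts > 0)
    gamma_cols = testable & (zero_frac <= zero_fraction_fallback)
    empir_cols = testable & ~gamma_cols

    if np.any(gamma_cols):
        idx = np.flatnonzero(gamma_cols)
        X = B[:, idx].astype(float) + 0.5
        mean = X.mean(axis=0)
        s = np.log(mean) - np.log(X).mean(axis=0)
        ok = s > 1e-12  # constant bootstrap columns cannot be fitted
        empir_cols[idx[~ok]] = True
        idx = idx[ok]
        if len(idx):
            mean, s = mean[ok], s[ok]
            # vectorized Newton on the profile likelihood, moment init
            k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
            for _ in range(40):
                f = np.log(k) - special.digamma(k) - s
                fp = 1.0 / k - special.polygamma(1, k)
                k = np.clip(k - f / fp, 1e-8, 1e12)
            scale = mean / k
            p[idx] = stats.gamma.sf(counts[idx] - 0.5, k, scale=scale)
            for pos, j in enumerate(idx):
                fits[j] = GammaParams(float(k[pos]), float(scale[pos]))

    for j in np.flatnonzero(empir_cols):
        p[j] = (1 + np.sum(B[:, j] >= counts[j])) / (n_boot + 1)

    null.position_null = fits
    return p


def correct_qvalues(
    pvals: np.ndarray,
    trident: np.ndarray,
    gate: float = TRIDENT_GATE,
) -> np.ndarray:
    """Benjamini–Hochberg q-values on Trident-gated columns only.

    Only columns with ``trident > gate`` (strict) enter the correction; the
    number of gated-in columns is the BH family size m. Gated-out columns get
    NaN so downstream reports can show "no q" explicitly. When no column
    passes the gate a warning is issued and all q are NaN.
    """
    pvals = np.asarray(pvals, dtype=float)
    trident = np.asarray(trident, dtype=float)
    if pvals.shape != trident.shape:
        raise ValueError("p-value and trident vectors differ in length")
    q = np.full(pvals.shape, np.nan)
    gated = trident > gate
    if not np.any(gated):
        warnings.warn("no column passes the Trident gate; no q-values computed")
        return q
    _, q_sub, _, _ = multipletests(pvals[gated], method="fdr_bh")
    q[gated] = q_sub
    return q


@dataclass
class HotspotResult:
    """Full per-column report plus the global randomness test.

    ``table`` has one row per consensus column with the observed count, the
    per-position p-value, the (possibly absent) q-value, the Trident score and
    the back-mapped contributing mutations. ``global_p`` is the lower-tail
    entropy test of the whole profile; ``nothing_to_test`` marks a run whose
    filtered profile carried no mutations.
    """

    table: pd.DataFrame
    global_p: Optional[float]
    H_obs: Optional[float]
    alpha: float
    nothing_to_test: bool = False

    def significant(self) -> pd.DataFrame:
        """Rows called as hotspots: q < alpha."""
        if self.nothing_to_test:
            return self.table
        return self.table[self.table["q"] < self.alpha]


def call_hotspots(
    profile: MutationProfile,
    consensus: ConsensusProfile,
    null: NullModel,
    aln: MultipleAlignment,
    alpha: float = 0.05,
    gate: float = TRIDENT_GATE,
) -> HotspotResult:
    """Assemble the per-column hotspot table with reverse-mapped contributors.

    Contributors come from the pooled profile's provenance, i.e. every
    class-filtered mutation is reported under its consensus column with its
    gene, original protein position, sample and tumor type. A profile with no
    mutations yields a clean "nothing to test" result rather than an error.
    """
    columns = np.arange(1, consensus.K + 1)
    base = pd.DataFrame(
        {
            "column": columns,
            "consensus_aa": list(consensus.consensus),
            "coverage": consensus.coverage,
            "trident": consensus.trident,
            "n_mut": profile.counts,
        }
    )
    try:
        H = shannon_entropy(profile)
    except NoMutationsError:
        base["p"] = np.nan
        base["q"] = np.nan
        base["contributors"] = [[] for _ in range(consensus.K)]
        return HotspotResult(base, None, None, alpha, nothing_to_test=True)

    gp = global_pvalue(H, null)
    p = position_pvalues(profile, null)
    q = correct_qvalues(p, consensus.trident, gate=gate)
    base["p"] = p
    base["q"] = q
    base["contributors"] = [list(c) for c in profile.provenance]
    return HotspotResult(base, gp, H, alpha)


def serialize_contributors(contributors: list[tuple[str, int, str, str]]) -> str:
    """``gene:pos:sample`` entries joined with ``;`` for TSV export."""
    return ";".join(f"{g}:{p}:{s}" for g, p, s, _t in contributors)
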