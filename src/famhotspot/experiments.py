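"""Reusable simulation experiments that measure the method's behavior.

Each function runs the package's own code paths on generated data with known
truth and returns summary numbers: null calibration of the global entropy
test, type-I behavior of the hotspot caller, power against a planted hotspot,
Gamma parameter recovery, the low-frequency rescue scenario (a column mutated
once per member is invisible to single-sequence scans but significant for the
family), and the silent-mutation negative control. The same functions back
the acceptance tests and the acceptance script so both measure identical
procedures.

Problem sizes default to desk scale (hundreds of seeded replicate runs on
K ~ 100-column profiles) — large enough for stable rates, small enough to run
in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import build_consensus, pool_mutations, reverse_map
from .hotspot import (
    build_null,
    correct_qvalues,
    fit_gamma,
    global_pvalue,
    position_pvalues,
    shannon_entropy,
)
from .mutation_io import MutationClass, MutationRecord
from .synthetic import CohortSpec, FamilySpec, generate_cohort, generate_family
from .workflow import analyze

__all__ = [
    "calibration_experiment",
    "power_experiment",
    "gamma_recovery",
    "rescue_experiment",
    "silent_control_experiment",
]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n)])


@dataclass
class CalibrationResult:
    ks_distance: float
    any_hotspot_rate: float
    n_runs: int


def calibration_experiment(
    seed: int,
    n_runs: int = 500,
    K: int = 100,
    N: int = 50,
    n_boot: int = 1000,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Type-I behavior with mutations placed by the null generator itself.

    Each run draws the observed profile from the same coverage-weighted
    multinomial the bootstrap uses (uniform coverage, all columns conserved),
    then runs the global entropy test and the per-position caller. Returns the
    KS distance of the global p-values from Uniform(0,1) and the fraction of
    runs with any q < alpha hotspot.
    """
    seeds = _spawn_seeds(seed, n_runs)
    weights = np.full(K, 1.0 / K)
    trident = np.ones(K)
    global_ps = np.empty(n_runs)
    any_hot = 0
    for r, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        counts = rng.multinomial(N, weights)
        null = build_null(weights, N, n_boot=n_boot, seed=int(s) + 1)
        global_ps[r] = global_pvalue(shannon_entropy(counts), null)
        p = position_pvalues(counts, null)
        q = correct_qvalues(p, trident)
        if np.any(q[~np.isnan(q)] < alpha):
            any_hot += 1
    ks = stats.kstest(global_ps, "uniform").statistic
    return CalibrationResult(float(ks), any_hot / n_runs, n_runs)


@dataclass
class PowerResult:
    power: float
    min_q_rate: float
    n_runs: int


def power_experiment(
    seed: int,
    n_runs: int = 200,
    K: int = 100,
    N: int = 50,
    hotspot_fraction: float = 0.3,
    n_boot: int = 1000,
    alpha: float = 0.05,
) -> PowerResult:
    """Detection of one planted hotspot carrying ``hotspot_fraction`` of N.

    Returns the fraction of runs where the planted column reaches q < alpha
    and the fraction where it is the minimum-q column.
    """
    seeds = _spawn_seeds(seed, n_runs)
    weights = np.full(K, 1.0 / K)
    trident = np.ones(K)
    n_hot = int(round(hotspot_fraction * N))
    detected = 0
    is_min = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        hot_col = int(rng.integers(K))
        counts = rng.multinomial(N - n_hot, weights)
        counts[hot_col] += n_hot
        null = build_null(weights, N, n_boot=n_boot, seed=int(s) + 1)
        p = position_pvalues(counts, null)
        q = correct_qvalues(p, trident)
        if q[hot_col] < alpha:
            detected += 1
        if np.nanargmin(q) == hot_col:
            is_min += 1
    return PowerResult(detected / n_runs, is_min / n_runs, n_runs)


@dataclass
class GammaRecovery:
    shape_rel_err: float
    scale_rel_err: float
    n: int


def gamma_recovery(
    seed: int, shape: float = 2.0, scale: float = 3.0, n: int = 10_000
) -> GammaRecovery:
    """Relative error of the Gamma MLE on draws from known parameters."""
    rng = np.random.default_rng(seed)
    x = rng.gamma(shape, scale, size=n)
    fit = fit_gamma(x)
    assert fit is not None
    return GammaRecovery(
        abs(fit.shape - shape) / shape, abs(fit.scale - scale) / scale, n
    )


@dataclass
class RescueResult:
    family_detection_rate: float
    single_sequence_false_rate: float
    success_rate: float
    n_runs: int


def rescue_experiment(
    seed: int,
    n_runs: int = 100,
    n_members: int = 12,
    length: int = 60,
    n_boot: int = 1000,
    alpha: float = 0.05,
) -> RescueResult:
    """The low-frequency rescue scenario: one mutation per member, same column.

    No member is significant on its own at n = 1, but pooling the family onto
    the consensus concentrates n_members mutations on one column. Success in a
    run = the planted column reaches q < alpha at family level AND no
    single-sequence scan of any member reports any significant column.
    """
    seeds = _spawn_seeds(seed, n_runs)
    fam_ok = 0
    single_clean = 0
    success = 0
    for s in seeds:
        fspec = FamilySpec(
            n_members=n_members, length=length, substitution_rate=0.15,
            indel_rate=0.02, seed=int(s),
        )
        records, true_aln = generate_family(fspec)
        consensus = build_consensus(true_aln)
        # plant: the best-covered, conserved column; one mutation per member
        rng = np.random.default_rng(int(s) + 7)
        candidates = np.flatnonzero(
            (consensus.coverage == n_members) & (consensus.trident > 0.5)
        )
        col = int(candidates[rng.integers(len(candidates))]) + 1
        # exactly one mutation per member, all on the same consensus column
        by_gene = {r.gene_symbol: r for r in records}
        muts = []
        for i, (gene, pos) in enumerate(reverse_map(true_aln, col)):
            ref = by_gene[gene].sequence[pos - 1]
            alt = next(a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref)
            muts.append(
                MutationRecord(gene, f"S{i + 1:03d}", "PANCAN",
                               MutationClass.MISSENSE, ref, pos, alt)
            )

        fam = analyze(records, muts, seed=int(s) + 29, aln=true_aln, n_boot=n_boot, q_alpha=alpha)
        fam_sig = fam.hotspots.significant()
        fam_hit = col in set(fam_sig["column"].astype(int))

        clean = True
        for k, rec in enumerate(records):
            gene_muts = [m for m in muts if m.gene_symbol == rec.gene_symbol]
            single = analyze([rec], gene_muts, seed=int(s) + 101 + k, n_boot=n_boot, q_alpha=alpha)
            if not single.hotspots.nothing_to_test and len(single.hotspots.significant()):
                clean = False
                break
        fam_ok += fam_hit
        single_clean += clean
        success += fam_hit and clean
    return RescueResult(
        fam_ok / n_runs, 1 - single_clean / n_runs, success / n_runs, n_runs
    )


@dataclass
class SilentControlResult:
    clean_rate: float
    n_runs: int


def silent_control_experiment(
    seed: int,
    n_runs: int = 100,
    n_boot: int = 1000,
    alpha: float = 0.05,
) -> SilentControlResult:
    """Negative control: uniform silent mutations, silent-only workflow.

    No hotspot is planted; a clean run reports zero significant columns.
    """
    seeds = _spawn_seeds(seed, n_runs)
    clean = 0
    for s in seeds:
        fspec = FamilySpec(n_members=8, length=120, seed=int(s))
        records, true_aln = generate_family(fspec)
        cspec = CohortSpec(
            n_samples=40,
            background_rate=1.0,
            mutation_class=MutationClass.SILENT,
            seed=int(s) + 3,
        )
        muts, _ = generate_cohort(cspec, records, true_aln)
        res = analyze(
            records,
            muts,
            seed=int(s) + 5,
            aln=true_aln,
            n_boot=n_boot,
            mutation_mode="silent_only",
            q_alpha=alpha,
        )
        if res.hotspots.nothing_to_test or len(res.hotspots.significant()) == 0:
            clean += 1
    return SilentControlResult(clean / n_runs, n_runs)
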