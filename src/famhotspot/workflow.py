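"""End-to-end workflows: hypothesis-driven, data-driven, and simulation.

``analyze`` is the in-memory pipeline (family records + mutation records ->
hotspot table) shared by everything else. ``run_hypothesis`` wraps it with
file I/O, ``run_datadriven`` sweeps all families named in a domain table plus
every gene's single-sequence analysis and unifies the significant hotspots,
``run_simulate`` writes synthetic inputs with their ground truth. Every run
writes a reproducibility sidecar (config, seed, version, input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    MultipleAlignment,
    MutationProfile,
    align_family,
    build_consensus,
    consensus_table,
    pool_mutations,
    write_aligned_fasta,
)
from .conservation import TRIDENT_GATE, check_homogeneity
from .cooccurrence import (
    build_presence_matrix,
    cooccur_analysis,
    pair_results_table,
)
from .hotspot import (
    HotspotResult,
    build_null,
    call_hotspots,
    sampling_weights,
    serialize_contributors,
)
from .mutation_io import (
    ConfigError,
    DataError,
    MutationRecord,
    ProteinRecord,
    filter_mutations,
    read_family,
    read_mutations,
    validate_against_sequences,
    write_mutations,
)
from .synthetic import CohortSpec, FamilySpec, generate_cohort, generate_family

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_hypothesis", "run_datadriven", "run_simulate"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one workflow run; seed is mandatory for stochastic steps."""

    mode: str = "hypothesis"  # hypothesis | datadriven | simulate
    fasta: Optional[str] = None
    mutations: Optional[str] = None
    domain_table: Optional[str] = None
    prealigned: Optional[str] = None
    family_filter: Optional[str] = None
    gene_filter: Optional[list[str]] = None
    mutation_mode: str = "missense_only"
    n_boot: int = 1000
    seed: int = 0
    trident_gate: float = TRIDENT_GATE
    q_alpha: float = 0.05
    homogeneity_threshold: float = 0.2
    backend: str = "builtin"
    aligner_executable: str = "clustalo"
    cooccurrence: bool = False
    outdir: str = "famhotspot_out"
    # simulate-mode specs
    family_spec: Optional[FamilySpec] = None
    cohort_spec: Optional[CohortSpec] = None

    def validate(self) -> None:
        if self.mode not in ("hypothesis", "datadriven", "simulate"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.trident_gate <= 1.0):
            raise ConfigError("trident_gate must be in [0, 1]")
        if not (0.0 < self.q_alpha < 1.0):
            raise ConfigError("q_alpha must be in (0, 1)")
        if not (0.0 <= self.homogeneity_threshold <= 1.0):
            raise ConfigError("homogeneity_threshold must be in [0, 1]")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")


@dataclass
class AnalysisResult:
    """Everything one family analysis produced."""

    hotspots: HotspotResult
    alignment: MultipleAlignment
    consensus: "object"
    profile: MutationProfile
    warnings: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    cooccurrence: Optional[pd.DataFrame] = None


def analyze(
    records: Sequence[ProteinRecord],
    mutations: Sequence[MutationRecord],
    *,
    seed: int,
    aln: Optional[MultipleAlignment] = None,
    backend: str = "builtin",
    prealigned: Optional[str] = None,
    aligner_executable: str = "clustalo",
    mutation_mode: str = "missense_only",
    n_boot: int = 1000,
    trident_gate: float = TRIDENT_GATE,
    q_alpha: float = 0.05,
    homogeneity_threshold: float = 0.2,
    run_cooccurrence: bool = False,
) -> AnalysisResult:
    """The hypothesis-driven pipeline on in-memory objects.

    Stages: homogeneity safety net -> alignment -> consensus + Trident ->
    class filter -> sequence validation -> pooling -> bootstrap null ->
    global and per-position tests -> hotspot table (-> optional
    co-occurrence of significant positions). ``aln`` short-circuits the
    alignment step with a precomputed MultipleAlignment.
    """
    homog = check_homogeneity(records, threshold=homogeneity_threshold)
    if aln is None:
        aln = align_family(
            records,
            backend=backend,
            aligned_fasta=prealigned,
            executable=aligner_executable,
        )
    consensus = build_consensus(aln)

    kept = filter_mutations(mutations, mutation_mode)
    kept, drop_diag = validate_against_sequences(kept, records)
    profile, pool_diag = pool_mutations(aln, kept)

    weights = sampling_weights(consensus)
    null = build_null(weights, max(profile.N, 1), n_boot=n_boot, seed=seed)
    result = call_hotspots(
        profile, consensus, null, aln, alpha=q_alpha, gate=trident_gate
    )

    cooc = None
    if run_cooccurrence and not result.nothing_to_test:
        sig = result.significant()
        if len(sig) >= 2:
            strata = sorted({m.tumor_type for m in kept})
            frames = []
            for stratum in strata:
                mat = build_presence_matrix(
                    kept, level="position", hotspots=result, aln=aln, stratum=stratum
                )
                if len(mat.features) >= 2:
                    frames.append(pair_results_table(cooccur_analysis(mat, alpha=q_alpha)))
            if frames:
                cooc = pd.concat(frames, ignore_index=True)

    return AnalysisResult(
        hotspots=result,
        alignment=aln,
        consensus=consensus,
        profile=profile,
        warnings=list(homog),
        diagnostics={
            "dropped_ref_mismatch": dict(drop_diag.dropped_by_gene),
            "pool_unknown_gene": pool_diag.unknown_gene,
            "pool_out_of_fragment": pool_diag.out_of_fragment,
        },
        cooccurrence=cooc,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_sidecar(outdir: Path, config: RunConfig, inputs: dict[str, str]) -> None:
    cfg = dataclasses.asdict(config)
    for key in ("family_spec", "cohort_spec"):
        if cfg.get(key) is not None:
            cfg[key] = {
                k: (v.value if hasattr(v, "value") else v) for k, v in cfg[key].items()
            }
    sidecar = {
        "tool": "famhotspot",
        "version": __version__,
        "config": cfg,
        "input_sha256": {k: _sha256(v) for k, v in inputs.items() if v},
    }
    (outdir / "run_sidecar.json").write_text(json.dumps(sidecar, indent=2, default=str))


def _hotspot_tsv(result: HotspotResult, path: Path) -> None:
    df = result.table.copy()
    df["contributors"] = df["contributors"].map(serialize_contributors)
    df.to_csv(path, sep="\t", index=False)


def run_hypothesis(config: RunConfig) -> AnalysisResult:
    """File-level hypothesis-driven workflow; artifacts land in config.outdir.

    On failure, partially written outputs are removed so a directory never
    holds a half-finished report.
    """
    config.validate()
    if not config.fasta or not config.mutations:
        raise ConfigError("hypothesis mode needs fasta and mutations paths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        records = read_family(
            config.fasta, config.domain_table, family_filter=config.family_filter
        )
        if config.gene_filter:
            wanted = set(config.gene_filter)
            records = [r for r in records if r.gene_symbol in wanted]
            if not records:
                raise DataError("gene_filter removed every record")
        muts, parse_diag = read_mutations(config.mutations)
        res = analyze(
            records,
            muts,
            seed=config.seed,
            backend=config.backend,
            prealigned=config.prealigned,
            aligner_executable=config.aligner_executable,
            mutation_mode=config.mutation_mode,
            n_boot=config.n_boot,
            trident_gate=config.trident_gate,
            q_alpha=config.q_alpha,
            homogeneity_threshold=config.homogeneity_threshold,
            run_cooccurrence=config.cooccurrence,
        )
        p = outdir / "hotspots.tsv"
        _hotspot_tsv(res.hotspots, p)
        written.append(p)
        p = outdir / "consensus.tsv"
        consensus_table(res.alignment, res.consensus).to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "alignment.fasta"
        write_aligned_fasta(res.alignment, p)
        written.append(p)
        if res.cooccurrence is not None:
            p = outdir / "cooccurrence.tsv"
            res.cooccurrence.to_csv(p, sep="\t", index=False)
            written.append(p)
        report = {
            "global_p": res.hotspots.global_p,
            "H_obs": res.hotspots.H_obs,
            "n_significant": int(len(res.hotspots.significant()))
            if not res.hotspots.nothing_to_test
            else 0,
            "nothing_to_test": res.hotspots.nothing_to_test,
            "n_mutations_pooled": res.profile.N,
            "parse_skipped": parse_diag.n_skipped,
            "homogeneity_warnings": [str(w) for w in res.warnings],
            "diagnostics": res.diagnostics,
        }
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, default=str))
        written.append(p)
        _write_sidecar(
            outdir,
            config,
            {
                "fasta": config.fasta,
                "mutations": config.mutations,
                "domain_table": config.domain_table or "",
            },
        )
        return res
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def run_datadriven(config: RunConfig) -> pd.DataFrame:
    """Data-driven sweep: per-family pooled analyses plus per-gene scans.

    Mutated genes are grouped by the family ids of their domain annotations;
    each family runs the pooled pipeline on domain-trimmed sequences and each
    mutated gene additionally runs a single-sequence scan (no alignment, no
    conservation gating in effect since a single sequence is perfectly
    conserved). All significant hotspots are unified into one ranked table
    with their support type. Families with no mappable mutation are skipped
    with a log line.
    """
    config.validate()
    if not config.fasta or not config.mutations or not config.domain_table:
        raise ConfigError("datadriven mode needs fasta, mutations and domain_table")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_records = read_family(config.fasta, config.domain_table)
    muts, _ = read_mutations(config.mutations)
    muts = filter_mutations(muts, config.mutation_mode)
    mutated_genes = {m.gene_symbol for m in muts}

    families: dict[str, list[ProteinRecord]] = {}
    for rec in all_records:
        if rec.gene_symbol not in mutated_genes:
            continue
        for dom in rec.domains:
            families.setdefault(dom.family_id, []).append(rec.trimmed(dom))

    unified: list[dict] = []
    seen: set[tuple] = set()

    for fam_id in sorted(families):
        recs = families[fam_id]
        fam_muts = [m for m in muts if m.gene_symbol in {r.gene_symbol for r in recs}]
        if not fam_muts:
            logger.info("family %s skipped: no mappable mutations", fam_id)
            continue
        res = analyze(
            recs,
            fam_muts,
            seed=config.seed,
            backend=config.backend,
            mutation_mode=config.mutation_mode,
            n_boot=config.n_boot,
            trident_gate=config.trident_gate,
            q_alpha=config.q_alpha,
            homogeneity_threshold=config.homogeneity_threshold,
        )
        _hotspot_tsv(res.hotspots, outdir / f"family_{fam_id}.tsv")
        if res.hotspots.nothing_to_test:
            continue
        for _, row in res.hotspots.significant().iterrows():
            for gene, pos, _s, _t in row["contributors"]:
                key = ("family", fam_id, int(row["column"]), gene, pos)
                if key in seen:
                    continue
                seen.add(key)
                unified.append(
                    {
                        "family_id": fam_id,
                        "column": int(row["column"]),
                        "gene_symbol": gene,
                        "position": pos,
                        "p": row["p"],
                        "q": row["q"],
                        "support": "family",
                    }
                )

    for gene in sorted(mutated_genes):
        recs = [r for r in all_records if r.gene_symbol == gene]
        if not recs:
            continue
        gene_muts = [m for m in muts if m.gene_symbol == gene]
        res = analyze(
            recs,
            gene_muts,
            seed=config.seed,
            mutation_mode=config.mutation_mode,
            n_boot=config.n_boot,
            trident_gate=config.trident_gate,
            q_alpha=config.q_alpha,
        )
        _hotspot_tsv(res.hotspots, outdir / f"gene_{gene}.tsv")
        if res.hotspots.nothing_to_test:
            continue
        for _, row in res.hotspots.significant().iterrows():
            key = ("gene", gene, int(row["column"]))
            if key in seen:
                continue
            seen.add(key)
            unified.append(
                {
                    "family_id": "",
                    "column": int(row["column"]),
                    "gene_symbol": gene,
                    "position": int(row["column"]),
                    "p": row["p"],
                    "q": row["q"],
                    "support": "single_sequence",
                }
            )

    table = pd.DataFrame(
        unified,
        columns=["family_id", "column", "gene_symbol", "position", "p", "q", "support"],
    ).sort_values(["q", "p"], kind="stable", ignore_index=True)
    table.to_csv(outdir / "unified_hotspots.tsv", sep="\t", index=False)
    _write_sidecar(
        outdir,
        config,
        {
            "fasta": config.fasta,
            "mutations": config.mutations,
            "domain_table": config.domain_table,
        },
    )
    return table


def run_simulate(config: RunConfig) -> dict[str, str]:
    """Write a synthetic family + cohort (and ground truth) to disk.

    The emitted files use exactly the formats the readers consume, so the
    output feeds ``run_hypothesis`` without edits.
    """
    config.validate()
    fspec = config.family_spec or FamilySpec(seed=config.seed)
    cspec = config.cohort_spec or CohortSpec(seed=config.seed + 1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, true_aln = generate_family(fspec)
    muts, truth = generate_cohort(cspec, records, true_aln)

    fasta = outdir / "family.fasta"
    with open(fasta, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_symbol}|{r.protein_id}\n{r.sequence}\n")
    aligned = outdir / "family_true_alignment.fasta"
    write_aligned_fasta(true_aln, aligned)
    mut_path = outdir / "mutations.tsv"
    write_mutations(muts, mut_path)
    truth_path = outdir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    _write_sidecar(outdir, config, {})
    return {
        "fasta": str(fasta),
        "prealigned": str(aligned),
        "mutations": str(mut_path),
        "ground_truth": str(truth_path),
    }
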