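"""End-to-end workflows: hypothesis, data-driven, simulate, CLI wiring."""

import json
from pathlib import Path

import pandas as pd
import pytest

from famhotspot import (
    CohortSpec,
    FamilySpec,
    RunConfig,
    analyze,
    generate_cohort,
    generate_family,
    run_datadriven,
    run_hypothesis,
    run_simulate,
)
from famhotspot.mutation_io import ConfigError, write_mutations


@pytest.fixture
def simulated_inputs(tmp_path):
    cfg = RunConfig(
        mode="simulate",
        outdir=str(tmp_path / "sim"),
        seed=3,
        family_spec=FamilySpec(n_members=8, length=120, seed=3),
        cohort_spec=CohortSpec(
            n_samples=40, background_rate=1.0, hotspot_columns=((30, 0.3),), seed=4
        ),
    )
    return run_simulate(cfg), tmp_path


class TestAnalyze:
    def test_planted_hotspot_detected_end_to_end(self, synthetic_family, planted_cohort):
        records, true_aln = synthetic_family
        muts, _ = planted_cohort
        res = analyze(records, muts, seed=5, aln=true_aln)
        sig = res.hotspots.significant()
        assert 30 in set(sig["column"].astype(int))
        assert res.hotspots.global_p < 0.05

    def test_single_gene_mode_no_alignment(self, synthetic_family):
        records, _ = synthetic_family
        rec = records[0]
        from tests.conftest import make_mutation

        muts = [make_mutation(rec.gene_symbol, sample=f"S{i}",
                              ref=rec.sequence[9], pos=10, alt="W") for i in range(15)]
        res = analyze([rec], muts, seed=6)
        assert res.alignment.K == len(rec.sequence)
        assert res.alignment.rows[0] == rec.sequence  # identity, no gaps
        assert 10 in set(res.hotspots.significant()["column"].astype(int))

    def test_no_mutations_is_clean(self, synthetic_family):
        records, true_aln = synthetic_family
        res = analyze(records, [], seed=7, aln=true_aln)
        assert res.hotspots.nothing_to_test


class TestRunHypothesis:
    def test_files_written_and_hotspot_found(self, simulated_inputs):
        paths, tmp = simulated_inputs
        out = tmp / "run1"
        cfg = RunConfig(
            mode="hypothesis", fasta=paths["fasta"], mutations=paths["mutations"],
            prealigned=paths["prealigned"], backend="prealigned",
            seed=11, outdir=str(out),
        )
        res = run_hypothesis(cfg)
        for name in ("hotspots.tsv", "consensus.tsv", "alignment.fasta",
                     "report.json", "run_sidecar.json"):
            assert (out / name).exists()
        truth = pd.read_csv(paths["ground_truth"], sep="\t")
        planted = truth.loc[truth["planted_hotspot"] > 0, "column"].iloc[0]
        assert planted in set(res.hotspots.significant()["column"].astype(int))
        sidecar = json.loads((out / "run_sidecar.json").read_text())
        assert sidecar["config"]["seed"] == 11 and sidecar["input_sha256"]

    def test_identical_seed_byte_identical_outputs(self, simulated_inputs):
        paths, tmp = simulated_inputs
        outs = []
        for name in ("a", "b"):
            out = tmp / name
            cfg = RunConfig(
                mode="hypothesis", fasta=paths["fasta"], mutations=paths["mutations"],
                prealigned=paths["prealigned"], backend="prealigned",
                seed=11, outdir=str(out),
            )
            run_hypothesis(cfg)
            outs.append(out)
        for name in ("hotspots.tsv", "consensus.tsv", "alignment.fasta"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_config_errors(self, tmp_path):
        with pytest.raises(ConfigError):
            run_hypothesis(RunConfig(mode="hypothesis", outdir=str(tmp_path)))
        with pytest.raises(ConfigError):
            RunConfig(mode="nope").validate()
        with pytest.raises(ConfigError):
            RunConfig(q_alpha=2.0).validate()


class TestRunDatadriven:
    @pytest.fixture
    def two_family_inputs(self, tmp_path):
        """Two disjoint families in one FASTA with a shared mutation file."""
        fam1, aln1 = generate_family(FamilySpec(n_members=5, length=80, seed=31))
        fam2, aln2 = generate_family(
            FamilySpec(n_members=4, length=60, gene_prefix="GENF", seed=32)
        )
        muts1, _ = generate_cohort(
            CohortSpec(n_samples=30, background_rate=0.5,
                       hotspot_columns=((20, 0.5),), seed=33), fam1, aln1)
        muts2, _ = generate_cohort(
            CohortSpec(n_samples=30, background_rate=1.0, seed=34), fam2, aln2)
        fasta = tmp_path / "all.fasta"
        with open(fasta, "w") as fh:
            for r in fam1 + fam2:
                fh.write(f">{r.gene_symbol}\n{r.sequence}\n")
        domains = tmp_path / "domains.tsv"
        with open(domains, "w") as fh:
            fh.write("gene_symbol\tfamily_id\tstart\tend\n")
            for r in fam1:
                fh.write(f"{r.gene_symbol}\tPFAAA\t1\t{len(r.sequence)}\n")
            for r in fam2:
                fh.write(f"{r.gene_symbol}\tPFBBB\t1\t{len(r.sequence)}\n")
        mpath = tmp_path / "muts.tsv"
        write_mutations(muts1 + muts2, mpath)
        return fasta, domains, mpath, tmp_path

    def test_structure_and_unified_table(self, two_family_inputs):
        fasta, domains, mpath, tmp = two_family_inputs
        out = tmp / "dd"
        cfg = RunConfig(mode="datadriven", fasta=str(fasta), mutations=str(mpath),
                        domain_table=str(domains), seed=41, outdir=str(out))
        table = run_datadriven(cfg)
        assert (out / "family_PFAAA.tsv").exists()
        assert (out / "family_PFBBB.tsv").exists()
        assert (out / "unified_hotspots.tsv").exists()
        assert set(table.columns) == {
            "family_id", "column", "gene_symbol", "position", "p", "q", "support"}
        # the planted family hotspot must appear with family support
        fam_rows = table[table["support"] == "family"]
        assert (fam_rows["family_id"] == "PFAAA").any()
        # unified rows are unique per (family, column, gene, position)
        assert not table.duplicated(
            subset=["family_id", "column", "gene_symbol", "position"]).any()

    def test_family_only_support_for_spread_mutations(self, tmp_path):
        """One mutation per member at a shared column: family support only."""
        fam, aln = generate_family(FamilySpec(n_members=12, length=60,
                                              substitution_rate=0.15,
                                              indel_rate=0.02, seed=51))
        from famhotspot import build_consensus
        cons = build_consensus(aln)
        col = int(np.argmax(cons.coverage)) + 1
        muts, _ = generate_cohort(
            CohortSpec(n_samples=12, background_rate=0.0,
                       hotspot_columns=((col, 1.0),), total_mutations=12, seed=52),
            fam, aln)
        fasta = tmp_path / "f.fasta"
        with open(fasta, "w") as fh:
            for r in fam:
                fh.write(f">{r.gene_symbol}\n{r.sequence}\n")
        domains = tmp_path / "d.tsv"
        with open(domains, "w") as fh:
            fh.write("gene_symbol\tfamily_id\tstart\tend\n")
            for r in fam:
                fh.write(f"{r.gene_symbol}\tPFCCC\t1\t{len(r.sequence)}\n")
        mpath = tmp_path / "m.tsv"
        write_mutations(muts, mpath)
        out = tmp_path / "dd"
        table = run_datadriven(RunConfig(
            mode="datadriven", fasta=str(fasta), mutations=str(mpath),
            domain_table=str(domains), seed=53, outdir=str(out)))
        assert len(table) > 0
        assert set(table["support"]) == {"family"}


import numpy as np  # noqa: E402  (used inside tests above)


class TestRunSimulate:
    def test_outputs_feed_hypothesis_without_edits(self, simulated_inputs):
        paths, tmp = simulated_inputs
        cfg = RunConfig(mode="hypothesis", fasta=paths["fasta"],
                        mutations=paths["mutations"], seed=61,
                        backend="prealigned", prealigned=paths["prealigned"],
                        outdir=str(tmp / "closure"))
        res = run_hypothesis(cfg)
        assert res.profile.N > 0

    def test_seed_stability(self, tmp_path):
        a = run_simulate(RunConfig(mode="simulate", seed=5, outdir=str(tmp_path / "x")))
        b = run_simulate(RunConfig(mode="simulate", seed=5, outdir=str(tmp_path / "y")))
        assert Path(a["fasta"]).read_text() == Path(b["fasta"]).read_text()
        assert Path(a["mutations"]).read_text() == Path(b["mutations"]).read_text()

    def test_truth_matches_cohort(self, simulated_inputs):
        paths, _ = simulated_inputs
        truth = pd.read_csv(paths["ground_truth"], sep="\t")
        muts = pd.read_csv(paths["mutations"], sep="\t")
        assert len(truth) == len(muts)


class TestCLI:
    def test_simulate_then_hypothesis(self, tmp_path):
        from click.testing import CliRunner

        from famhotspot.cli import main

        runner = CliRunner()
        r = runner.invoke(main, ["simulate", "--seed", "2", "--outdir", str(tmp_path / "s")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "hypothesis",
            "--fasta", str(tmp_path / "s" / "family.fasta"),
            "--mutations", str(tmp_path / "s" / "mutations.tsv"),
            "--prealigned", str(tmp_path / "s" / "family_true_alignment.fasta"),
            "--backend", "prealigned",
            "--seed", "3", "--outdir", str(tmp_path / "h"),
        ])
        assert r.exit_code == 0, r.output
        assert "global p" in r.output

    def test_config_error_exit_code(self, tmp_path):
        from click.testing import CliRunner

        from famhotspot.cli import main

        r = CliRunner().invoke(main, ["hypothesis", "--seed", "1",
                                      "--outdir", str(tmp_path)])
        assert r.exit_code == 2
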