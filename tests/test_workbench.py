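"""I/O round trips, config serialization, the CLI and the demo bundle."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from sagkit import io as skio
from sagkit import synthdata, workbench
from sagkit.cli import main as cli_main
from sagkit.config import PipelineConfig


class TestFastaRoundTrip:
    def test_wrapped_and_unwrapped_parse_identically(self, tmp_path):
        seqs = {"a": "ACGT" * 60, "b": "TTGGCCAA" * 25}
        wrapped, flat = tmp_path / "w.fasta", tmp_path / "f.fasta"
        skio.write_fasta(seqs, wrapped, width=60)
        flat.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        assert skio.read_fasta(wrapped) == skio.read_fasta(flat) == seqs

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nACGT\n>x\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            skio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            skio.read_fasta(p)


class TestNewickRoundTrip:
    def test_quoted_labels_preserved(self, tmp_path):
        from skbio import TreeNode

        p = tmp_path / "t.nwk"
        tree = TreeNode.read(["('phylotype A':1.5,'phylotype B':2.25);"])
        skio.write_newick(tree, p)
        back = skio.read_newick(p)
        assert {t.name for t in back.tips()} == {"phylotype A", "phylotype B"}
        assert {t.length for t in back.tips()} == {1.5, 2.25}


class TestCsvSchemas:
    def test_events_round_trip(self, tmp_path):
        ev = synthdata.gen_cytometry_sample(synthdata.CytoSimParams(n_events=500, seed=1))
        p = tmp_path / "ev.csv"
        skio.write_events_csv(ev, p)
        back = skio.read_events_csv(p)
        assert len(back) == len(ev)
        np.testing.assert_allclose(back["ssc_log10"], ev["ssc_log10"], rtol=1e-9)

    def test_missing_column_error_names_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"event_id": [1], "ssc_log10": [2.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="fl1_log10"):
            skio.read_events_csv(p)

    def test_kinetics_round_trip(self, tmp_path):
        plate = synthdata.gen_mda_plate(
            synthdata.MdaSimParams(n_wells_1cell=4, n_wells_0cell=2, n_wells_10cell=1, seed=2)
        )
        p = tmp_path / "kin.csv"
        skio.write_kinetics_csv(plate, p)
        back = skio.read_kinetics_csv(p)
        assert set(back.truth["well"]) == set(plate.truth["well"])
        np.testing.assert_allclose(
            back.curves["fluorescence"], plate.curves["fluorescence"], rtol=1e-9
        )

    def test_annotations_round_trip_and_duplicate_check(self, tmp_path):
        _, _, annot = synthdata.gen_genome_and_sag(
            synthdata.GenomeSimParams(genome_length_bp=20_000, n_cscg=5, seed=3)
        )
        p = tmp_path / "annot.csv"
        skio.write_annotations_csv(annot, p)
        back = skio.read_annotations_csv(p)
        assert list(back["gene_id"]) == list(annot["gene_id"])
        dup = pd.concat([annot, annot.iloc[[0]]], ignore_index=True)
        skio.write_annotations_csv(dup, p)
        with pytest.raises(ValueError, match="duplicate gene_id"):
            skio.read_annotations_csv(p)

    def test_distance_matrix_round_trip(self, tmp_path):
        from skbio import DistanceMatrix

        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        dm = DistanceMatrix(d, ids=["x", "y", "z"])
        p = tmp_path / "dm.csv"
        skio.write_distance_csv(dm, p)
        back = skio.read_distance_csv(p)
        assert list(back.ids) == ["x", "y", "z"]
        np.testing.assert_allclose(back.data, d)


class TestConfig:
    def test_yaml_round_trip_unchanged(self, tmp_path):
        cfg = PipelineConfig(seed=42)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = PipelineConfig.from_yaml(p)
        assert back == cfg
        assert back.content_hash() == cfg.content_hash()

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(rank_sum_alpha=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(ani_coverage_floor=0.0)

    def test_stage_seeds_distinct_and_stable(self):
        cfg = PipelineConfig(seed=7)
        s1 = cfg.stage_seed("cytometry")
        s2 = cfg.stage_seed("mda")
        assert s1 != s2
        assert s1 == PipelineConfig(seed=7).stage_seed("cytometry")
        assert 0 <= s1 < 2**31


def bundle_digest(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
        if p.is_file()
    }


@pytest.fixture(scope="module")
def demo_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    cfg = PipelineConfig(seed=5)
    summary = workbench.run_demo(cfg, out)
    return cfg, out, summary


class TestDemo:
    def test_repeat_run_is_byte_identical(self, demo_run, tmp_path):
        cfg, out, _ = demo_run
        out2 = tmp_path / "again"
        workbench.run_demo(PipelineConfig(seed=5), out2)
        assert bundle_digest(out) == bundle_digest(out2)

    def test_labeled_percentage_near_nominal(self, demo_run):
        _, _, summary = demo_run
        assert summary["labeled_event_percent"] == pytest.approx(0.1, rel=0.5)

    def test_live_killed_fold_reported(self, demo_run):
        _, _, summary = demo_run
        assert summary["fold_infinite"] or summary["live_killed_fold"] >= 50

    def test_manifest_records_version_and_config_hash(self, demo_run):
        cfg, out, _ = demo_run
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.content_hash()
        assert manifest["seed"] == 5
        assert "version" in manifest

    def test_outputs_round_trip_through_readers(self, demo_run):
        _, out, _ = demo_run
        skio.read_events_csv(out / "events_live.csv")
        skio.read_kinetics_csv(out / "mda_kinetics.csv")
        skio.read_fasta(out / "amplicons.fasta")
        skio.read_newick(out / "phylotype_nj.nwk")
        skio.read_distance_csv(out / "unifrac.csv")


class TestCli:
    def test_completeness_subcommand_prints_printed_example(self):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["completeness", "--assembly-bp", "2100000", "--n-found", "151"],
        )
        assert res.exit_code == 0
        assert "55.3%" in res.output
        assert "3.8 Mb" in res.output

    def test_simulate_then_gate_and_qc(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--seed", "3", "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["gate", str(tmp_path / "events_live.csv")])
        assert res.exit_code == 0
        assert "events" in res.output
        res = runner.invoke(cli_main, ["mda-qc", str(tmp_path / "mda_kinetics.csv")])
        assert res.exit_code == 0, res.output
        assert "pass at alpha=0.05: True" in res.output

    def test_phylotype_subcommand_writes_assignments(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out", str(tmp_path)])
        out = tmp_path / "phylo"
        res = runner.invoke(
            cli_main,
            [
                "phylotype",
                str(tmp_path / "amplicons.fasta"),
                "--libraries",
                str(tmp_path / "libraries.csv"),
                "--out",
                str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        assignments = pd.read_csv(out / "assignments.csv")
        assert {"seq_id", "phylotype"} <= set(assignments.columns)
        comp = pd.read_csv(out / "composition.csv")
        sums = comp.groupby("library")["rel_abundance"].sum()
        assert np.allclose(sums, 1.0)


class TestCompareAssemblyDir:
    def test_all_pairs_table_on_synthetic_assemblies(self, tmp_path, markov_assembly_factory):
        # plumbing for the deposited-assembly comparison: same-taxon pair has
        # defined, high ANI and high signature correlation
        a = markov_assembly_factory("verruco", 1, 2, 15_000)
        seq = "".join(a.contigs.values())
        b_contigs = {"c0": seq[:14000]}
        from sagkit.synthdata import GenomeAssembly

        b = GenomeAssembly("verruco_sub", b_contigs)
        c = markov_assembly_factory("bacteroid", 2, 2, 15_000)
        for asm, name in ((a, "a"), (b, "b"), (c, "c")):
            skio.write_assembly(asm, tmp_path / f"{name}.fasta")
        table = workbench.compare_assembly_dir(tmp_path)
        assert len(table) == 3
        ab = table[(table["genome_a"] == "a") & (table["genome_b"] == "b")].iloc[0]
        assert ab["ani_ab"] == pytest.approx(100.0, abs=0.5)
        assert ab["tetra_r"] > 0.8
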