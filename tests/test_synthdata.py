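"""Generator contracts: mixture structure, truth labels, determinism."""

import numpy as np
import pandas as pd
import pytest

from sagkit import synthdata
from sagkit.synthdata import (
    CytoSimParams,
    GenomeSimParams,
    MdaSimParams,
    SeqSimParams,
)


class TestCytometrySim:
    def test_zero_labeled_fraction_gives_no_labeled_events(self):
        ev = synthdata.gen_cytometry_sample(
            CytoSimParams(n_events=5000, labeled_fraction=0.0, seed=4)
        )
        assert (ev["truth_class"] == "labeled").sum() == 0

    def test_labeled_count_within_binomial_bound(self):
        params = CytoSimParams(n_events=100_000, seed=1)
        ev = synthdata.gen_cytometry_sample(params)
        n = (ev["truth_class"] == "labeled").sum()
        mean = params.n_events * params.labeled_fraction
        sd = np.sqrt(mean * (1 - params.labeled_fraction))
        assert abs(n - mean) <= 3 * sd

    def test_killed_attenuation_ratio_near_configured_fold(self):
        live_total = killed_total = 0
        for seed in range(40):
            params = CytoSimParams(n_events=100_000, seed=seed)
            live = synthdata.gen_cytometry_sample(params, killed=False)
            killed = synthdata.gen_cytometry_sample(params, killed=True)
            live_total += (live["truth_class"] == "labeled").sum()
            killed_total += (killed["truth_class"] == "labeled").sum()
        ratio = live_total / killed_total
        se_rel = np.sqrt(1 / live_total + 1 / killed_total)
        assert abs(ratio - 60) <= 3 * se_rel * 60

    def test_every_event_carries_truth_label(self):
        ev = synthdata.gen_cytometry_sample(CytoSimParams(n_events=2000, seed=0))
        assert set(ev["truth_class"]) <= {"unlabeled", "labeled", "bead", "noise"}
        assert ev["truth_class"].notna().all()

    def test_bead_count_consistent_with_declared_volume(self):
        params = CytoSimParams(n_events=10_000, seed=9)
        ev = synthdata.gen_cytometry_sample(params)
        n_beads = (ev["truth_class"] == "bead").sum()
        lam = params.bead_conc_per_ml * params.acquired_volume_ml
        assert abs(n_beads - lam) <= 4 * np.sqrt(lam)

    def test_deterministic_given_seed(self):
        params = CytoSimParams(n_events=3000, seed=11)
        a = synthdata.gen_cytometry_sample(params)
        b = synthdata.gen_cytometry_sample(params)
        pd.testing.assert_frame_equal(a, b)

    def test_nonfinite_channel_param_rejected_naming_field(self):
        chans = {k: dict(v) for k, v in synthdata.DEFAULT_CHANNEL_PARAMS.items()}
        chans["labeled"]["fl1_mean"] = float("nan")
        with pytest.raises(ValueError, match="fl1_mean"):
            CytoSimParams(channel_params=chans)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"labeled_fraction": -0.1},
            {"labeled_fraction": 1.5},
            {"killed_attenuation": 0.5},
            {"n_events": 0},
            {"dilution_factor": 0.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CytoSimParams(**kwargs)


class TestMdaSim:
    def test_noiseless_half_max_crossing_equals_truth_midpoint(self):
        plate = synthdata.gen_mda_plate(
            MdaSimParams(noise_sd=0.0, well_jitter_sd_hours=0.0, seed=2)
        )
        t = plate.curves[plate.curves["well"] == "W000"]
        mid = plate.truth.loc[plate.truth["well"] == "W000", "true_midpoint_hours"].item()
        f = t["fluorescence"].to_numpy()
        half = f[0] + (f.max() - f[0]) / 2
        k = int(np.argmax(f >= half))
        tt = t["t_hours"].to_numpy()
        crossing = tt[k - 1] + (tt[k] - tt[k - 1]) * (half - f[k - 1]) / (f[k] - f[k - 1])
        assert crossing == pytest.approx(mid, abs=0.05)

    def test_class_midpoint_ordering_by_template(self):
        plate = synthdata.gen_mda_plate(MdaSimParams(seed=7))
        med = plate.truth.groupby("template_cells")["true_midpoint_hours"].median()
        assert med[0] > med[1] > med[10]

    def test_default_layout_has_315_66_3_wells(self):
        plate = synthdata.gen_mda_plate(MdaSimParams(seed=0))
        counts = plate.truth["template_cells"].value_counts()
        assert counts[1] == 315 and counts[0] == 66 and counts[10] == 3

    def test_bad_timestep_rejected(self):
        with pytest.raises(ValueError):
            MdaSimParams(timestep_hours=0.0)


class TestSeqSim:
    def test_zero_within_divergence_gives_identical_members(self):
        seqs, truth = synthdata.gen_phylotype_library(
            SeqSimParams(within_divergence=0.0, seed=5)
        )
        for _, grp in truth.groupby("phylotype"):
            assert len({seqs[s] for s in grp["seq_id"]}) == 1

    def test_one_member_per_phylotype_counts(self):
        seqs, truth = synthdata.gen_phylotype_library(
            SeqSimParams(n_phylotypes=7, seqs_per_phylotype=1, seed=1)
        )
        assert len(seqs) == 7
        assert truth["phylotype"].nunique() == 7

    def test_members_carry_exact_within_divergence(self):
        p = SeqSimParams(within_divergence=0.005, seq_length=1000, seed=3)
        seqs, truth = synthdata.gen_phylotype_library(p)
        # reconstruct: members of the same phylotype differ from each other at
        # most at 2 * round(d*L) sites
        for _, grp in truth.groupby("phylotype"):
            members = [seqs[s] for s in grp["seq_id"]]
            for i in range(1, len(members)):
                diff = sum(a != b for a, b in zip(members[0], members[i]))
                assert diff <= 2 * round(0.005 * 1000)

    def test_inseparable_parameters_rejected(self):
        with pytest.raises(ValueError, match="separation|exceed"):
            SeqSimParams(within_divergence=0.009, between_divergence=0.005)

    def test_alphabet_is_uppercase_acgt(self):
        seqs, _ = synthdata.gen_phylotype_library(SeqSimParams(seed=8))
        assert set("".join(seqs.values())) <= set("ACGT")


class TestGenomeSim:
    def test_full_completeness_single_contig_equals_genome(self):
        full, partial, _ = synthdata.gen_genome_and_sag(
            GenomeSimParams(
                genome_length_bp=20_000, completeness=1.0, n_contigs=1, n_cscg=10, seed=3
            )
        )
        assert partial.total_length == full.total_length
        assert next(iter(partial.contigs.values())) == next(iter(full.contigs.values()))

    def test_partial_length_matches_completeness(self):
        _, partial, _ = synthdata.gen_genome_and_sag(
            GenomeSimParams(genome_length_bp=1_000_000, completeness=0.5, seed=6)
        )
        assert abs(partial.total_length - 500_000) <= 0.01 * 500_000

    def test_segments_are_non_overlapping_genome_slices(self):
        full, partial, _ = synthdata.gen_genome_and_sag(
            GenomeSimParams(genome_length_bp=50_000, completeness=0.4, n_contigs=5, n_cscg=20, seed=2)
        )
        genome = next(iter(full.contigs.values()))
        segments = partial.truth["segments"]
        for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
            assert e1 <= s2
        for (s, e), contig in zip(segments, partial.contigs.values()):
            assert genome[s:e] == contig

    def test_annotation_gh_fraction_near_nominal(self):
        _, _, annot = synthdata.gen_genome_and_sag(
            GenomeSimParams(genome_length_bp=2_000_000, gh_frequency=0.012, seed=4)
        )
        frac = (annot["class"] == "GH").mean()
        n = len(annot)
        assert abs(frac - 0.012) <= 3 * np.sqrt(0.012 * 0.988 / n)

    def test_same_profile_more_similar_than_cross_profile(self):
        from sagkit import genome_compare

        def sig(profile, seed):
            full, _, _ = synthdata.gen_genome_and_sag(
                GenomeSimParams(genome_length_bp=100_000, taxon_profile=profile, seed=seed)
            )
            return genome_compare.tetra_zscores(full)

        a1, a2, b1 = sig("verruco", 1), sig("verruco", 2), sig("bacteroid", 1)
        same = genome_compare.tetra_correlation(a1, a2)
        cross = genome_compare.tetra_correlation(a1, b1)
        assert cross < same

    def test_infeasible_contig_count_rejected(self):
        with pytest.raises(ValueError):
            GenomeSimParams(genome_length_bp=10_000, completeness=0.0001, n_contigs=50)

    def test_deterministic_given_seed(self):
        p = GenomeSimParams(genome_length_bp=30_000, n_cscg=10, seed=12)
        a_full, a_part, a_annot = synthdata.gen_genome_and_sag(p)
        b_full, b_part, b_annot = synthdata.gen_genome_and_sag(p)
        assert a_full.contigs == b_full.contigs
        assert a_part.contigs == b_part.contigs
        pd.testing.assert_frame_equal(a_annot, b_annot)


class TestDetectedFamilies:
    def test_full_assembly_detects_every_family(self):
        _, partial, annot = synthdata.gen_genome_and_sag(
            GenomeSimParams(
                genome_length_bp=50_000, completeness=1.0, n_contigs=1, n_cscg=30, seed=1
            )
        )
        found = synthdata.detected_families(partial, annot)
        assert len(found) == 30

    def test_detection_fraction_tracks_completeness(self):
        _, partial, annot = synthdata.gen_genome_and_sag(
            GenomeSimParams(genome_length_bp=500_000, completeness=0.5, n_cscg=273, seed=9)
        )
        frac = len(synthdata.detected_families(partial, annot)) / 273
        assert abs(frac - 0.5) < 0.12
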