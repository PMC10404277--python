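"""Synthetic transcriptomes, fraction counts, RPF reads: planted-truth closure."""

import numpy as np
import pandas as pd
import pytest

from polyte.models import START_CODON
from polyte.simulate import (
    DEFAULT_RPF_LENGTH_DIST,
    SimulationDesign,
    expected_fraction_means,
    generate_fraction_counts,
    generate_luciferase_table,
    generate_rpf_reads,
    generate_transcriptome,
    make_spikein_reference,
)
from polyte.uorf import CONTAINED, OVERLAP_OUT_OF_FRAME, find_uorfs

from conftest import brute_force_uorf_scan


class TestTranscriptome:
    def test_deterministic_under_seed(self):
        a_t, a_ann = generate_transcriptome(10, seed=42)
        b_t, b_ann = generate_transcriptome(10, seed=42)
        assert [t.sequence for t in a_t] == [t.sequence for t in b_t]
        pd.testing.assert_frame_equal(a_ann, b_ann)
        c_t, _ = generate_transcriptome(10, seed=43)
        assert [t.sequence for t in a_t] != [t.sequence for t in c_t]

    def test_no_uorf_spec_means_no_augs_in_any_utr(self):
        transcripts, _ = generate_transcriptome(50, seed=1)
        for t in transcripts:
            assert find_uorfs(t) == []
            assert brute_force_uorf_scan(t) == []  # independent AUG scan

    def test_invariants_hold_for_every_transcript(self):
        transcripts, _ = generate_transcriptome(25, seed=2)
        for t in transcripts:
            assert 0 <= t.cds_start < t.cds_end <= len(t.sequence)
            assert (t.cds_end - t.cds_start) % 3 == 0
            assert t.sequence[t.cds_start : t.cds_start + 3] == START_CODON

    @pytest.mark.parametrize("kind", ["contained", "overlapping_out_of_frame"])
    def test_planted_uorf_rediscovered(self, kind):
        spec = [{"gene_id": "gene002", "kind": kind}]
        transcripts, ann = generate_transcriptome(5, uorf_spec=spec, seed=3)
        t = next(x for x in transcripts if x.gene_id == "gene002")
        (u,) = find_uorfs(t)
        expected = CONTAINED if kind == "contained" else OVERLAP_OUT_OF_FRAME
        assert u.overlap_class == expected
        uorf_ann = ann[(ann.transcript_id == t.transcript_id) & (ann.feature == "uORF")]
        assert len(uorf_ann) == 1
        assert int(uorf_ann["start0"].iloc[0]) == u.start
        others = [x for x in transcripts if x.gene_id != "gene002"]
        assert all(find_uorfs(x) == [] for x in others)

    def test_overlapping_uorf_geometry(self):
        spec = [{"gene_id": "gene001", "kind": "overlapping_out_of_frame"}]
        transcripts, _ = generate_transcriptome(3, uorf_spec=spec, seed=4)
        t = transcripts[0]
        (u,) = find_uorfs(t)
        end = u.stop_end if u.stop_end is not None else len(t)
        assert end > t.cds_start
        assert (u.start - t.cds_start) % 3 != 0

    def test_two_uorf_transcript_like_xrp1(self):
        spec = [
            {"gene_id": "gene001", "kind": "contained"},
            {"gene_id": "gene001", "kind": "overlapping_out_of_frame"},
        ]
        transcripts, _ = generate_transcriptome(
            2, utr5_len_range=(40, 80), uorf_spec=spec, seed=5
        )
        u1, u2 = find_uorfs(transcripts[0])
        assert u1.overlap_class == CONTAINED
        assert u2.overlap_class == OVERLAP_OUT_OF_FRAME
        assert u1.start < u2.start

    def test_infeasible_uorf_spec_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_transcriptome(
                2,
                utr5_len_range=(2, 5),
                uorf_spec=[{"gene_id": "gene001", "kind": "overlapping_out_of_frame"}],
            )

    def test_unknown_kind_error(self):
        with pytest.raises(ValueError, match="kind"):
            generate_transcriptome(2, uorf_spec=[{"gene_id": "gene001", "kind": "weird"}])


class TestFractionCounts:
    def test_zero_dispersion_counts_equal_rounded_means(self):
        design = SimulationDesign(
            mean_depth=333.0, dispersion=0.0,
            te_effects={"g2": 1.0}, rna_effects={"g3": -1.0},
            library_scale_factors={"mutant_polysome_rep1": 1.7},
            seed=9,
        )
        genes = ["g1", "g2", "g3"]
        cm, _ = generate_fraction_counts(genes, design)
        mu = expected_fraction_means(genes, design)
        np.testing.assert_array_equal(cm.counts.to_numpy(), np.rint(mu.to_numpy()))

    def test_spikein_ratio_tracks_scale_factors_exactly(self):
        design = SimulationDesign(
            genotypes=("control",), fractions=("total",),
            replicates_per_condition=2, mean_depth=100.0, dispersion=0.0,
            library_scale_factors={"control_total_rep2": 2.0},
            spikein_unit_counts=1.0, seed=0,
        )
        ref = make_spikein_reference(10, span_log2=4, total_amount=4000)
        cm, _ = generate_fraction_counts(["g1"], design, ref)
        spikes = cm.spikes
        ratio = spikes["control_total_rep2"] / spikes["control_total_rep1"]
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-2)  # rounding only

    def test_spikein_counts_independent_of_genotype(self):
        design = SimulationDesign(mean_depth=100.0, dispersion=0.0, seed=0,
                                  te_effects={"g1": 3.0}, rna_effects={"g1": 2.0})
        ref = make_spikein_reference(5, span_log2=2, total_amount=1000)
        cm, _ = generate_fraction_counts(["g1"], design, ref)
        spikes = cm.spikes
        for col in spikes.columns:
            np.testing.assert_array_equal(spikes[col], spikes[spikes.columns[0]])

    def test_nb_mean_variance_relation(self):
        design = SimulationDesign(
            genotypes=("control",), fractions=("total",),
            replicates_per_condition=4000, mean_depth=200.0, dispersion=0.1,
            seed=12,
        )
        cm, _ = generate_fraction_counts(["g1"], design)
        x = cm.counts.loc["g1"].to_numpy()
        mu, alpha = 200.0, 0.1
        assert x.mean() == pytest.approx(mu, rel=0.05)
        assert x.var() == pytest.approx(mu + alpha * mu**2, rel=0.1)

    def test_determinism_and_seed_sensitivity(self):
        design = SimulationDesign(seed=7, mean_depth=50.0)
        a, _ = generate_fraction_counts(["g1", "g2"], design)
        b, _ = generate_fraction_counts(["g1", "g2"], design)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        c, _ = generate_fraction_counts(
            ["g1", "g2"], SimulationDesign(seed=8, mean_depth=50.0)
        )
        assert not a.counts.equals(c.counts)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(mean_depth=0.0)
        with pytest.raises(ValueError):
            SimulationDesign(dispersion=-0.1)
        with pytest.raises(ValueError):
            SimulationDesign(replicates_per_condition=0)
        with pytest.raises(ValueError):
            SimulationDesign(library_scale_factors={"x": -1.0})


class TestRpfReads:
    @pytest.fixture
    def transcript(self):
        transcripts, _ = generate_transcriptome(
            1, utr5_len_range=(60, 60), cds_codons_range=(100, 100), seed=6
        )
        return transcripts[0]

    def test_all_reads_start_in_cds_when_weighted_fully(self, transcript):
        regions = transcript.regions()
        reads = generate_rpf_reads(transcript, regions, {"CDS": 1.0}, 500, seed=1)
        a, b = regions["CDS"]
        assert ((reads["start"] >= a) & (reads["start"] < b)).all()

    def test_zero_reads_gives_empty_set(self, transcript):
        reads = generate_rpf_reads(transcript, transcript.regions(), {"CDS": 1.0}, 0)
        assert len(reads) == 0

    def test_region_fraction_within_binomial_tolerance(self, transcript):
        regions = transcript.regions()
        n = 10000
        reads = generate_rpf_reads(
            transcript, regions, {"five_prime_UTR": 0.8, "CDS": 0.2}, n, seed=2
        )
        a, b = regions["five_prime_UTR"]
        frac = ((reads["start"] >= a) & (reads["start"] < b)).mean()
        tol = 3 * np.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.8) <= tol

    def test_lengths_follow_given_distribution(self, transcript):
        reads = generate_rpf_reads(
            transcript, transcript.regions(), {"CDS": 1.0}, 2000,
            length_dist={30: 0.5, 31: 0.5}, seed=3,
        )
        assert set(reads["length"]) == {30, 31}

    def test_footprints_fit_transcript(self, transcript):
        reads = generate_rpf_reads(
            transcript, transcript.regions(), {"three_prime_UTR": 1.0}, 300, seed=4
        )
        assert ((reads["start"] + reads["length"]) <= len(transcript.sequence)).all()

    def test_region_too_short_for_footprint_error(self, transcript):
        with pytest.raises(ValueError, match="too short"):
            generate_rpf_reads(
                transcript,
                {"tail": (len(transcript.sequence) - 2, len(transcript.sequence))},
                {"tail": 1.0},
                10,
                length_dist={35: 1.0},
            )

    def test_weights_must_sum_to_one(self, transcript):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_rpf_reads(transcript, transcript.regions(), {"CDS": 0.5}, 10)

    def test_default_length_distribution_spans_25_to_35(self, transcript):
        assert set(DEFAULT_RPF_LENGTH_DIST) == set(range(25, 36))
        reads = generate_rpf_reads(transcript, transcript.regions(), {"CDS": 1.0},
                                   3000, seed=5)
        assert reads["length"].min() >= 25 and reads["length"].max() <= 35


def test_luciferase_table_planted_effects_recovered(rng):
    table = generate_luciferase_table(
        {"NC": 1.0, "wt": 0.4}, n_replicates=200, cv=0.05, seed=21
    )
    from polyte.reporter import relative_luciferase

    rel = relative_luciferase(table, "NC")
    wt = rel.loc[rel.construct_id == "wt", "relative_activity"].mean()
    assert wt == pytest.approx(0.4, rel=0.05)
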