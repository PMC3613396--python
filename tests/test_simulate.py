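"""Generator self-consistency: planted truth, determinism, negative controls."""

import numpy as np
import pytest

from dpsevolve import promoters
from dpsevolve.simulate import (Cohort, generate_cohort, generate_ct_table,
                                generate_replicon, make_ss, mutate_to_identity,
                                write_cohort)

PAT = promoters.compile_pattern(promoters.SIGB_PATTERN_SPEC)

SMALL = dict(length=1_500_000, n_genes=20, arm_threshold=400_000)


class TestMutateToIdentity:
    def test_target_100_identity(self):
        seq = "MKTEEQLRAFIEKVGGDLSW"
        assert mutate_to_identity(seq, 100.0, seed=0) == seq

    def test_exact_substitution_count(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        out = mutate_to_identity(seq, 97.0, seed=1)
        assert sum(a != b for a, b in zip(seq, out)) == 3
        assert len(out) == len(seq)

    def test_granularity_error_short_sequence(self):
        with pytest.raises(ValueError, match="unreachable"):
            mutate_to_identity("MKTEEQLRAF", 97.0, seed=0)  # len 10: 90 or 100 only

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            mutate_to_identity("MKTEEQLRAF", 0.0, seed=0)


class TestMakeSS:
    def test_five_helices_with_bc(self):
        from dpsevolve import classify
        ss = make_ss("dpsB", 3, 2)
        segs = classify.helix_segments(ss)
        assert len(segs) == 5
        assert classify.is_dps_signature(segs) == (True, True)
        assert classify.tail_lengths(ss) == (3, 2)

    def test_bfr_four_helices(self):
        from dpsevolve import classify
        ss = make_ss("bfr", 3, 3)
        segs = classify.helix_segments(ss)
        assert len(segs) == 4
        assert classify.is_dps_signature(segs) == (False, False)


class TestGenerateReplicon:
    def test_planted_motif_found_others_clean(self):
        rep, truth = generate_replicon(
            "gx", dps_complement=("dpsA", "dpsB"), plant_motif_for={"dpsA"},
            seed=11, **SMALL)
        from dpsevolve.context import orient_replicon
        rep = orient_replicon(rep)
        for g in rep.genes_sorted():
            call = promoters.sigb_call(g, rep, PAT)
            if g.id == "gx_dpsA":
                assert call.positive
                assert call.distance_to_orf == \
                    truth.planted_motifs["gx_dpsA"]["distance"]
            else:
                assert not call.positive

    def test_empty_complement(self):
        rep, truth = generate_replicon("gy", dps_complement=(), seed=1, **SMALL)
        assert not any(g.family.startswith("dps") for g in rep.genes)
        assert truth.planted_motifs == {} and truth.planted_families == {}

    def test_same_seed_byte_identical(self):
        r1, _ = generate_replicon("gz", seed=42, **SMALL)
        r2, _ = generate_replicon("gz", seed=42, **SMALL)
        assert r1.sequence == r2.sequence and r1.genes == r2.genes

    def test_dnaa_central_after_orientation(self):
        from dpsevolve.context import orient_replicon
        rep, _ = generate_replicon("gc", seed=5, **SMALL)
        rep = orient_replicon(rep)
        mid = rep.dnaa.midpoint
        assert abs(mid - rep.length / 2) <= 0.05 * rep.length

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown dps families"):
            generate_replicon("ge", dps_complement=("dpsQ",), seed=0, **SMALL)


class TestGenerateCohort:
    def test_conserved_core_synteny_100(self, small_cohort):
        from dpsevolve.context import (neighbourhood, orient_replicon,
                                       synteny_consensus)
        nbs = []
        for g in small_cohort.genomes:
            rep = orient_replicon(g.replicon)
            focal = rep.gene(f"{g.id}_dpsB")
            nbs.append(neighbourhood(focal, rep, k=3))
        prof = synteny_consensus(nbs)
        assert all(f == 100.0 for _, f in prof.offsets.values())

    def test_shuffled_arm_synteny_low(self, small_cohort):
        from dpsevolve.context import (mean_consensus_frequency, neighbourhood,
                                       orient_replicon, synteny_consensus)
        nbs = []
        for g in small_cohort.genomes:
            rep = orient_replicon(g.replicon)
            focal = rep.gene(f"{g.id}_dpsB2")
            nbs.append(neighbourhood(focal, rep, k=3))
        prof = synteny_consensus(nbs)
        assert mean_consensus_frequency(prof) < 60.0

    def test_seed_determinism(self):
        c1 = generate_cohort(n_genomes=2, seed=8, **SMALL)
        c2 = generate_cohort(n_genomes=2, seed=8, **SMALL)
        assert c1.genomes[0].replicon.sequence == c2.genomes[0].replicon.sequence
        assert [p.sequence for p in c1.genomes[1].proteome] == \
            [p.sequence for p in c2.genomes[1].proteome]
        assert c1.ct_records == c2.ct_records

    def test_negative_control_no_motifs_no_calls(self):
        c = generate_cohort(n_genomes=2, plant_motif_for=(), seed=9, **SMALL)
        from dpsevolve.context import orient_replicon
        for g in c.genomes:
            rep = orient_replicon(g.replicon)
            for locus in rep.genes_sorted():
                assert not promoters.sigb_call(locus, rep, PAT).positive

    def test_paralog_identity_targets_in_bounds(self, small_cohort):
        for a, b, t in small_cohort.truth.planted_paralog_pairs:
            assert 85.0 < t < 100.0

    def test_dpsb2_requires_dpsb(self):
        with pytest.raises(ValueError, match="dpsB2"):
            generate_cohort(n_genomes=2, complements=[("dpsB2",), ("dpsB",)],
                            seed=0, **SMALL)

    def test_write_cohort_is_text_only(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort, tmp_path / "c")
        assert (tmp_path / "c" / "truth.json").exists()
        for entry in manifest["genomes"]:
            raw = (tmp_path / "c" / entry["fasta"]).read_bytes()
            assert raw.decode("ascii")  # plain text round-trips


class TestGenerateCtTable:
    def test_exact_ratio_at_zero_noise(self):
        from dpsevolve.expression import summarize
        rows = generate_ct_table({"g": 8.0}, efficiency=2.0, noise_sd=0.0,
                                 n_reps=3, seed=0)
        assert summarize(rows)[0].ratio_mean == pytest.approx(8.0)

    def test_flat_truth_all_ones(self):
        from dpsevolve.expression import summarize
        rows = generate_ct_table({"a": 1.0, "b": 1.0}, efficiency=2.0,
                                 noise_sd=0.0, n_reps=3, seed=0)
        assert all(f.ratio_mean == pytest.approx(1.0) for f in summarize(rows))

    def test_reference_fold_change_one_by_construction(self):
        from dpsevolve.expression import summarize
        rows = generate_ct_table({"a": 4.0}, efficiency=2.0, noise_sd=0.0,
                                 n_reps=2, seed=0)
        ref = next(f for f in summarize(rows, include_reference=True)
                   if f.gene == "hrdB")
        assert ref.ratio_mean == pytest.approx(1.0)
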