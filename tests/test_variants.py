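import numpy as np
import pandas as pd
import pytest

from aneuscreen import synthetic_data as sd
from aneuscreen.core import GeneAnnotation, Genome, ValidationError, revcomp
from aneuscreen.pileup import ChromPileup, Pileup
from aneuscreen.variants import (
    CallerParams,
    call_differences,
    call_mutations,
    classify_effect,
    classify_effects,
    integrate_variants,
    refine_reference,
    unique_mutations,
)
from Bio.Seq import Seq


def _site_pileup(ref_seq: str, depth: np.ndarray, alt_base: str, alt_counts: np.ndarray) -> Pileup:
    """One-chromosome pileup where site i has alt_counts[i] reads of
    alt_base and the rest reference."""
    n = len(ref_seq)
    ref = np.frombuffer(ref_seq.encode(), dtype="S1").copy()
    counts = np.zeros((4, n), dtype=np.int64)
    from aneuscreen.pileup import base_indices

    ref_idx = base_indices(ref)
    alt_idx = "ACGT".index(alt_base)
    counts[ref_idx, np.arange(n)] = depth - alt_counts
    counts[alt_idx, np.arange(n)] += alt_counts
    return Pileup({"c": ChromPileup(ref=ref, depth=depth.astype(np.int64), counts=counts)})


class TestCallThreshold:
    def test_boundary_inclusive_at_90_percent(self):
        ref = Genome({"c": "AA"})
        plp = _site_pileup("AA", np.array([10, 10]), "T", np.array([9, 8]))
        calls = call_differences(plp, ref)
        assert calls["pos"].tolist() == [1]
        assert calls["fraction"].iloc[0] == pytest.approx(0.9)

    def test_exhaustive_enumeration_matches_direct_inequality(self):
        """All (depth <= 20, alt <= depth) pairs reproduce the plain rule
        alt/depth >= 0.9 and depth >= min_depth."""
        pairs = [(d, a) for d in range(0, 21) for a in range(0, d + 1)]
        depth = np.array([d for d, _ in pairs])
        alt = np.array([a for _, a in pairs])
        ref = Genome({"c": "A" * len(pairs)})
        plp = _site_pileup(ref.sequences["c"], depth, "G", alt)
        called = set(call_differences(plp, ref)["pos"])
        for i, (d, a) in enumerate(pairs):
            expected = d >= 10 and a / d >= 0.9 if d else False
            assert ((i + 1) in called) == expected, (d, a)

    def test_ceil_rule_across_depths_10_to_200(self):
        """For every depth d, ceil(0.9 d) alternate reads are called and one
        fewer is not (when that fraction drops below 0.9)."""
        depths = np.arange(10, 201)
        ks = np.ceil(0.9 * depths).astype(int)
        n = len(depths)
        ref = Genome({"c": "C" * (2 * n)})
        depth = np.concatenate([depths, depths])
        alt = np.concatenate([ks, ks - 1])
        plp = _site_pileup(ref.sequences["c"], depth, "A", alt)
        called = set(call_differences(plp, ref)["pos"])
        for i, (d, k) in enumerate(zip(depths, ks)):
            assert (i + 1) in called
            below = (k - 1) / d < 0.9
            assert ((n + i + 1) in called) == (not below)

    def test_split_alternates_below_threshold_not_called(self):
        ref = Genome({"c": "A"})
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[1, 0] = 5  # C
        counts[2, 0] = 5  # G
        plp = Pileup({"c": ChromPileup(
            ref=np.frombuffer(b"A", dtype="S1").copy(),
            depth=np.array([10], dtype=np.int64), counts=counts)})
        assert len(call_differences(plp, ref)) == 0

    def test_reference_mismatch_reports_coordinate(self, small_genome):
        plp = sd.simulate_pileup(sd.MutantModel.euploid(small_genome), small_genome, 20)
        plp.chroms["chrA"].ref[41] = b"N"
        with pytest.raises(ValidationError, match="chrA:42"):
            call_differences(plp, small_genome)


class TestIntegrateVariants:
    def test_snv_substituted_in_place(self):
        g = Genome({"c": "ACGTACGT"})
        vs = pd.DataFrame(
            [{"chrom": "c", "pos": 3, "ref": "G", "alt": "A", "type": "snv",
              "fraction": 1.0, "depth": 10}]
        )
        new, cmap = integrate_variants(g, vs)
        assert new.sequences["c"] == "ACATACGT"
        assert cmap.map("c", 8) == 8

    def test_deletion_shifts_downstream_coordinates(self):
        # 2 bp deletion of positions p+1..p+2 (anchored at p=3)
        g = Genome({"c": "ACGTACGTAC"})
        vs = pd.DataFrame(
            [{"chrom": "c", "pos": 3, "ref": "GTA", "alt": "G", "type": "deletion",
              "fraction": 1.0, "depth": 10}]
        )
        new, cmap = integrate_variants(g, vs)
        assert new.sequences["c"] == "ACGCGTAC"
        assert len(new.sequences["c"]) == 8
        assert cmap.map("c", 8) == 6  # old p+5 -> new p+3
        assert cmap.map("c", 4) is None and cmap.map("c", 5) is None

    def test_insertion_shifts_downstream_coordinates(self):
        g = Genome({"c": "ACGTAC"})
        vs = pd.DataFrame(
            [{"chrom": "c", "pos": 2, "ref": "C", "alt": "CTT", "type": "insertion",
              "fraction": 1.0, "depth": 10}]
        )
        new, cmap = integrate_variants(g, vs)
        assert new.sequences["c"] == "ACTTGTAC"
        assert cmap.map("c", 2) == 2 and cmap.map("c", 3) == 5

    def test_overlapping_variants_rejected(self):
        g = Genome({"c": "ACGTACGT"})
        vs = pd.DataFrame(
            [
                {"chrom": "c", "pos": 3, "ref": "GTA", "alt": "G", "type": "deletion",
                 "fraction": 1.0, "depth": 10},
                {"chrom": "c", "pos": 4, "ref": "T", "alt": "A", "type": "snv",
                 "fraction": 1.0, "depth": 10},
            ]
        )
        with pytest.raises(ValidationError, match="overlap"):
            integrate_variants(g, vs)

    def test_integration_order_independent(self):
        g = Genome({"c": "ACGTACGTACGT"})
        rows = [
            {"chrom": "c", "pos": 2, "ref": "C", "alt": "CAA", "type": "insertion",
             "fraction": 1.0, "depth": 10},
            {"chrom": "c", "pos": 6, "ref": "CGT", "alt": "C", "type": "deletion",
             "fraction": 1.0, "depth": 10},
            {"chrom": "c", "pos": 10, "ref": "C", "alt": "T", "type": "snv",
             "fraction": 1.0, "depth": 10},
        ]
        fwd, _ = integrate_variants(g, pd.DataFrame(rows))
        rev, _ = integrate_variants(g, pd.DataFrame(rows[::-1]))
        assert fwd.sequences == rev.sequences


class TestRefinement:
    def test_identical_progenitor_converges_immediately(self, small_genome):
        provider = lambda g: sd.simulate_pileup(
            sd.MutantModel.euploid(small_genome), g, 100, 0.0, "none", 1
        )
        ref = refine_reference(small_genome, provider)
        assert ref.converged and ref.cycles_run == 1
        assert ref.variants_per_cycle == [0]
        assert ref.genome == small_genome

    def test_planted_differences_recovered_exactly(self, small_genome):
        rng = np.random.default_rng(5)
        snvs = []
        for pos in rng.choice(np.arange(1000, 19000), 5, replace=False):
            ref_b = small_genome.base_at("chrA", int(pos))
            snvs.append(sd.PlannedSNV("chrA", int(pos), ref_b,
                                      [b for b in "ACGT" if b != ref_b][0]))
        prog = sd.plant_events(small_genome, sd.MutationPlan(snvs=snvs))
        provider = lambda g: sd.simulate_pileup(prog, g, 100, 0.0, "none", 2)
        refined = refine_reference(small_genome, provider)
        assert refined.genome == prog.genome
        assert refined.converged and refined.cycles_run <= 2

    def test_refinement_is_a_fixed_point(self, cohort42):
        fx, refined, _ = cohort42
        provider = lambda g: sd.simulate_pileup(fx.progenitor_model, g, 100, 0.0, "none", 7)
        again = refine_reference(refined.genome, provider)
        assert again.cycles_run == 1 and again.variants_per_cycle == [0]
        assert again.genome == refined.genome

    def test_adversarial_provider_stops_at_ten_cycles(self):
        g = Genome({"c": "ACGTACGTAC"})

        def provider(genome: Genome) -> Pileup:
            # always report one fresh difference at position 1
            seq = genome.sequences["c"]
            alt = "A" if seq[0] != "A" else "C"
            depth = np.full(len(seq), 100, dtype=np.int64)
            alts = np.zeros(len(seq), dtype=np.int64)
            alts[0] = 100
            return _site_pileup(seq, depth, alt, alts)

        refined = refine_reference(g, provider)
        assert refined.cycles_run == 10
        assert not refined.converged
        assert all(c == 1 for c in refined.variants_per_cycle)


class TestCallMutations:
    def test_noiseless_planted_snv_full_support(self, small_genome):
        ref_b = small_genome.base_at("chrB", 9000)
        mut = sd.plant_events(
            small_genome,
            sd.MutationPlan(snvs=[sd.PlannedSNV("chrB", 9000, ref_b,
                                                "A" if ref_b != "A" else "T")]),
        )
        plp = sd.simulate_pileup(mut, small_genome, 100, 0.0, "none")
        calls = call_mutations(plp, small_genome, mutant_id="m1")
        assert len(calls) == 1
        assert calls["fraction"].iloc[0] == 1.0
        assert calls["mutant_id"].iloc[0] == "m1"

    def test_snv_with_five_percent_errors_still_called(self, small_genome):
        ref_b = small_genome.base_at("chrB", 9000)
        mut = sd.plant_events(
            small_genome,
            sd.MutationPlan(snvs=[sd.PlannedSNV("chrB", 9000, ref_b,
                                                "A" if ref_b != "A" else "T")]),
        )
        plp = sd.simulate_pileup(mut, small_genome, 100, 0.05, "none", seed=11)
        calls = call_mutations(plp, small_genome, mutant_id="m1")
        snv = calls[(calls["chrom"] == "chrB") & (calls["pos"] == 9000)]
        assert len(snv) == 1
        assert snv["fraction"].iloc[0] >= 0.90

    def test_half_fraction_site_not_called(self):
        # a variant on one copy of a disomic chromosome: 50% support
        ref = Genome({"c": "A" * 20})
        depth = np.full(20, 200, dtype=np.int64)
        alts = np.zeros(20, dtype=np.int64)
        alts[4] = 100
        plp = _site_pileup(ref.sequences["c"], depth, "G", alts)
        assert len(call_mutations(plp, ref)) == 0


class TestEffectClassification:
    def test_snv_outside_features_is_intergenic(self):
        g = Genome({"c": "ATGGGATAAACGTACGT"})
        ann = GeneAnnotation(pd.DataFrame(
            [("g1", "c", 1, 9, "+", "gene")],
            columns=["feature_id", "chrom", "start", "end", "strand", "feature_type"]))
        call = {"chrom": "c", "pos": 12, "ref": "G", "alt": "T", "type": "snv"}
        assert classify_effect(call, ann, g) == "intergenic"

    def test_third_position_gga_to_ggg_is_synonymous(self):
        g = Genome({"c": "ATGGGATAA"})
        ann = GeneAnnotation(pd.DataFrame(
            [("g1", "c", 1, 9, "+", "gene")],
            columns=["feature_id", "chrom", "start", "end", "strand", "feature_type"]))
        call = {"chrom": "c", "pos": 6, "ref": "A", "alt": "G", "type": "snv"}
        assert classify_effect(call, ann, g) == "synonymous"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_nine_substitutions_match_translation_oracle(self, strand):
        """Every single-base substitution of the middle codon classifies the
        same as brute-force translation of the whole gene."""
        mrna = "ATGGGATAC" + "TAA"  # M G Y *
        gene_seq = mrna if strand == "+" else revcomp(mrna)
        g = Genome({"c": "AC" + gene_seq + "GT"})
        ann = GeneAnnotation(pd.DataFrame(
            [("g1", "c", 3, 3 + len(gene_seq) - 1, strand, "gene")],
            columns=["feature_id", "chrom", "start", "end", "strand", "feature_type"]))
        for pos in range(3, 3 + len(gene_seq)):
            ref_b = g.base_at("c", pos)
            for alt in "ACGT":
                if alt == ref_b:
                    continue
                call = {"chrom": "c", "pos": pos, "ref": ref_b, "alt": alt, "type": "snv"}
                got = classify_effect(call, ann, g)
                # oracle: translate the full gene before and after
                seq = list(g.sequences["c"])
                seq[pos - 1] = alt
                mutated_slice = "".join(seq[2 : 2 + len(gene_seq)])
                before = str(Seq(gene_seq if strand == "+" else revcomp(gene_seq)).translate())
                after = str(Seq(mutated_slice if strand == "+" else revcomp(mutated_slice)).translate())
                expected = "synonymous" if before == after else "nonsynonymous"
                assert got == expected, (strand, pos, ref_b, alt)

    def test_indels_not_applicable(self, small_genome):
        ann = sd.generate_annotation(small_genome, 5, seed=1)
        call = {"chrom": "chrA", "pos": 100, "ref": "A", "alt": "AT", "type": "insertion"}
        assert classify_effect(call, ann, small_genome) == "not_applicable"


class TestUniqueMutations:
    def test_shared_call_counted_once_and_disjoint_sum(self):
        base = {"ref": "A", "alt": "T", "type": "snv", "fraction": 1.0,
                "depth": 100, "effect": "nonsynonymous"}
        rows = [dict(base, chrom="c", pos=p, mutant_id="m1") for p in (1, 2, 3)]
        rows += [dict(base, chrom="c", pos=p, mutant_id="m2") for p in (10, 11, 12, 13)]
        rows += [dict(base, chrom="c", pos=1, mutant_id="m2")]  # shared with m1
        uniq, counts = unique_mutations(pd.DataFrame(rows))
        assert len(uniq) == 7
        assert counts == {"nonsynonymous": 7}

    def test_cohort_class_counts_match_planted_truth(self, cohort42):
        fx, _, cohort_calls = cohort42
        uniq, counts = unique_mutations(cohort_calls)
        assert len(uniq) == len(fx.planted_unique) == 39
        planted_counts = fx.planted_unique["effect_class"].value_counts().to_dict()
        assert counts == planted_counts


def test_noiseless_recovery_is_exact(cohort42):
    """On noiseless 100x pileups every planted point mutation is recovered
    per mutant with zero false positives."""
    fx, _, cohort_calls = cohort42
    truth = {
        (mid, t.chrom, t.start, t.alt)
        for mid, model in fx.mutants
        for t in model.truth
        if t.event_type == "snv"
    }
    called = {
        (r["mutant_id"], r["chrom"], int(r["pos"]), r["alt"])
        for _, r in cohort_calls[cohort_calls["type"] == "snv"].iterrows()
    }
    assert called == truth
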