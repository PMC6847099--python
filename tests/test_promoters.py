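import numpy as np
import pandas as pd
import pytest

from tirscope.promoters import (
    GibbsParams,
    MotifHit,
    PromoterModel,
    build_promoter_model,
    derive_consensus,
    filter_probable_promoters,
    find_candidate_elements,
    leader_lengths,
    spacing_histogram,
)
from tirscope.sequence_io import GeneAnnotation, TSSRecord
from tirscope.simulate import generate_promoter_set


class TestConsensusScan:
    def test_exact_seed_match_found_with_full_score(self):
        seqs = {"g1": "C" * 30 + "TAGGTTTG" + "ACGTA"}
        hits = find_candidate_elements(seqs)
        assert len(hits) == 1
        h = hits[0]
        assert h.element_seq == "TAGGTTTG"
        assert h.score == 6.0
        assert h.spacing == 5

    def test_all_a_sequence_yields_no_hit(self):
        assert find_candidate_elements({"g1": "A" * 50}) == []

    def test_tie_broken_toward_tss(self):
        seqs = {"g1": "TACCTTTG" + "AAAA" + "TAGGTTTG" + "AA"}
        (hit,) = find_candidate_elements(seqs)
        assert hit.spacing == 2  # the downstream (TSS-proximal) match wins

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_elements({})

    def test_planted_elements_recovered(self):
        seqs, truth = generate_promoter_set(seed=9, n_planted=200, n_decoys=50)
        hits = {h.gene_id: h for h in find_candidate_elements(seqs)}
        recovered = sum(
            1
            for sid, (element, spacing) in truth.items()
            if sid in hits
            and hits[sid].element_seq == element
            and hits[sid].spacing == spacing
        )
        assert recovered / len(truth) >= 0.95


class TestSpacingAndFilter:
    def make_hits(self, spacings):
        return [
            MotifHit(f"g{i}", "TACTTTTG", s, 6.0, 40 - s)
            for i, s in enumerate(spacings)
        ]

    def test_histogram_proportions(self):
        assert spacing_histogram(self.make_hits([4, 4, 4])) == {4: 1.0}
        hist = spacing_histogram(self.make_hits([4, 5, 4, 5]))
        assert hist == {4: 0.5, 5: 0.5}

    def test_filter_keeps_only_4_and_5(self):
        hits = self.make_hits([3, 4, 5, 6, 7])
        kept = filter_probable_promoters(hits)
        assert [h.spacing for h in kept] == [4, 5]
        assert filter_probable_promoters([]) == []
        assert filter_probable_promoters(self.make_hits([7, 7])) == []

    def test_filter_is_idempotent_subset(self):
        hits = self.make_hits([3, 4, 5, 5, 9])
        once = filter_probable_promoters(hits)
        assert filter_probable_promoters(once) == once
        assert set(h.gene_id for h in once) <= set(h.gene_id for h in hits)

    def test_planted_spacing_mixture_recovered(self):
        seqs, truth = generate_promoter_set(
            seed=3, n_planted=400, n_decoys=0, spacing_probs={4: 0.7, 5: 0.3}
        )
        hist = spacing_histogram(find_candidate_elements(seqs))
        assert hist[4] == pytest.approx(0.7, abs=0.08)  # multinomial 3 sigma
        assert hist[5] == pytest.approx(0.3, abs=0.08)


class TestPromoterModel:
    def test_identical_elements_give_unit_columns(self):
        seqs = {"g1": "A" * 30 + "TACTTTTG" + "AAAA",
                "g2": "C" * 30 + "TACTTTTG" + "GGGG"}
        hits = find_candidate_elements(seqs)
        model = build_promoter_model(hits, seqs)
        assert model.positions == list(range(-12, -4))
        assert (model.frequencies.max(axis=0) == 1.0).all()
        assert derive_consensus(model) == "TACTTTTG"

    def test_flank_columns_lose_coverage_without_error(self):
        seqs = {"g1": "TACTTTTG" + "AAAA", "g2": "G" + "TACTTTTG" + "AAAA"}
        hits = find_candidate_elements(seqs)
        model = build_promoter_model(hits, seqs, flank=3)
        first_flank = model.counts[model.positions[0]]
        assert first_flank.sum() < len(hits)  # truncated at sequence bounds

    def test_planted_model_recovers_planting_distribution(self):
        seqs, _ = generate_promoter_set(seed=5, n_planted=300, n_decoys=0)
        hits = filter_probable_promoters(find_candidate_elements(seqs))
        model = build_promoter_model(hits, seqs)
        # invariant positions T A . . T T T G
        for pos, base in zip([-12, -11, -8, -7, -6, -5], "TATTTG"):
            assert model.frequencies.loc[base, pos] > 0.97
        # H positions: A/C/T near 1/3 each, G near zero
        for pos in (-10, -9):
            assert model.frequencies.loc["G", pos] < 0.03
            for base in "ACT":
                assert model.frequencies.loc[base, pos] == pytest.approx(
                    1 / 3, abs=0.1
                )


class TestDeriveConsensus:
    def make_model(self, columns):
        freqs = pd.DataFrame(columns, index=list("ACGT"))
        freqs.columns = list(range(-12, -12 + len(columns.keys())))
        counts = (freqs * 100).astype(int)
        return PromoterModel(8, list(freqs.columns), counts, freqs, 100)

    def test_invariant_h_and_n_columns(self):
        model = self.make_model(
            {
                0: [0.02, 0.005, 0.005, 0.97],  # T invariant
                1: [0.35, 0.32, 0.02, 0.31],  # G absent -> H
                2: [0.25, 0.25, 0.25, 0.25],  # N
            }
        )
        model.positions = [0, 1, 2]
        model.frequencies.columns = [0, 1, 2]
        consensus = derive_consensus(model, element_only=False)
        assert consensus == "THN"

    def test_threshold_validation(self):
        model = self.make_model({0: [1.0, 0.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            derive_consensus(model, invariant_threshold=0.4)

    def test_synthetic_planting_recovers_tahhtttg(self):
        seqs, _ = generate_promoter_set(seed=1, n_planted=200, n_decoys=50)
        hits = filter_probable_promoters(find_candidate_elements(seqs))
        model = build_promoter_model(hits, seqs)
        assert derive_consensus(model) == "TAHHTTTG"


class TestGibbsSampler:
    def test_fixed_seed_is_reproducible(self):
        seqs, _ = generate_promoter_set(seed=2, n_planted=40, n_decoys=0)
        params = GibbsParams(iterations=600, restarts=3, seed=7)
        a = find_candidate_elements(seqs, mode="gibbs", gibbs=params)
        b = find_candidate_elements(seqs, mode="gibbs", gibbs=params)
        assert a == b

    def test_recovers_planted_motif_across_seeds(self):
        """On planted-motif data most seeds land within Hamming 1 of the truth."""
        seqs, _ = generate_promoter_set(seed=4, n_planted=60, n_decoys=0)

        def hamming(a, b):
            return sum(x != y for x, y in zip(a, b))

        good = 0
        for seed in range(10):
            params = GibbsParams(iterations=900, restarts=5, seed=seed)
            hits = find_candidate_elements(seqs, mode="gibbs", gibbs=params)
            model = build_promoter_model(hits, seqs)
            consensus = derive_consensus(model)
            good += hamming(consensus, "TAHHTTTG") <= 1
        assert good >= 8


class TestLeaderLengths:
    def make_gene(self, start=100, end=160, strand="+"):
        return GeneAnnotation("g", "c", start, end, strand)

    def test_leaderless_and_definition(self):
        gene = self.make_gene()
        leaders, _ = leader_lengths([TSSRecord("g", "c", 100, "+")], [gene])
        assert leaders["g"] == 0  # TSS on the start codon itself
        leaders, _ = leader_lengths([TSSRecord("g", "c", 66, "+")], [gene])
        assert leaders["g"] == 33  # 34 nt upstream -> 33 intervening nt

    def test_reverse_strand(self):
        gene = self.make_gene(strand="-")
        # start codon first base at genomic 159; TSS 34 nt downstream-in-genome
        leaders, _ = leader_lengths([TSSRecord("g", "c", 193, "-")], [gene])
        assert leaders["g"] == 33

    def test_summary_statistics(self):
        genes = [GeneAnnotation(f"g{i}", "c", 100, 160, "+") for i in range(4)]
        tss = [
            TSSRecord("g0", "c", 100, "+"),  # leader 0
            TSSRecord("g1", "c", 94, "+"),  # leader 5
            TSSRecord("g2", "c", 79, "+"),  # leader 20
            TSSRecord("g3", "c", 59, "+"),  # leader 40
        ]
        leaders, summary = leader_lengths(tss, genes, threshold=10)
        assert leaders == {"g0": 0, "g1": 5, "g2": 20, "g3": 40}
        assert summary["mean_leader"] == pytest.approx(16.25)
        assert summary["fraction_over_threshold"] == pytest.approx(0.5)

    def test_synthetic_leaders_recover_planted_distribution(self, small_bundle):
        _, bundle, _, _ = small_bundle
        truth = bundle.ground_truth.frame()
        leaders, summary = leader_lengths(bundle.tss_records, bundle.annotations)
        observed = pd.Series(leaders)
        planted = truth.loc[observed.index, "leader"]
        assert (observed == planted).all()
        assert summary["mean_leader"] == pytest.approx(planted.mean())
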