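import numpy as np
import pytest

from fragile_rss import (
    DnaSequence,
    RSSConsensus,
    RSSModel,
    ScanParams,
    mismatch_score,
    model_score,
    nick_site,
    revcomp,
    scan_rss,
)
from fragile_rss.synthetic_data import gen_rss_sequence

from oracles import brute_force_scan


def hit_tuples(hits):
    return {
        (h.strand, h.heptamer_start, h.spacer_length, h.heptamer_mismatches, h.nonamer_mismatches)
        for h in hits
    }


class TestScanOnBenchSubstrates:
    def test_canonical_substrate_has_unique_exact_12rss(self, sequences):
        """The canonical control carries exactly one perfect heptamer 17 nt
        from the 5' end with a 12-nt spacer to a perfect nonamer."""
        hits = scan_rss(sequences["AKN1"], params=ScanParams(0, 0, strands="top"))
        assert len(hits) == 1
        h = hits[0]
        assert h.heptamer_start == 17      # = bases preceding the heptamer
        assert h.spacer_length == 12
        assert h.nonamer_start == 36
        assert (h.heptamer_mismatches, h.nonamer_mismatches) == (0, 0)
        assert h.heptamer_seq == "CACAGTG" and h.nonamer_seq == "ACAAAAACC"

    @pytest.mark.parametrize("name", ["DG13", "DG27", "MS20"])
    def test_rss_free_controls_scan_empty(self, sequences, name):
        """Negative-control substrates contain no qualifying cryptic RSS
        under default mismatch budgets (confirmed by brute force)."""
        seq = sequences[name]
        assert scan_rss(seq, params=ScanParams(strands="top")) == []
        assert brute_force_scan(seq.bases, strands="top") == set()

    def test_amy1b_region_offers_both_12_and_23_arrangements(self, sequences):
        hits = scan_rss(sequences["AP96"], params=ScanParams(strands="top"))
        spacers = {h.spacer_length for h in hits}
        assert spacers == {12, 23}
        assert all(h.heptamer_start == 20 for h in hits)

    def test_best_cryptic_hit_on_camk2d_substrate(self, sequences):
        # the cryptic nonamer sits 14 nt from the heptamer, so a spacer
        # tolerance of 2 around the canonical 12 is needed to call it
        hits = scan_rss(sequences["AP92"], params=ScanParams(3, 4, 2, True, "top"))
        assert hits and hits[0].heptamer_start == 20
        assert hits[0].heptamer_seq == "CACAGCA"
        assert hits[0].heptamer_mismatches == 2
        assert nick_site(hits[0]) == 20


class TestScanProperties:
    def test_brute_force_oracle_equivalence_on_random_sequences(self):
        """Exact set equality with an independent triple-loop enumeration on
        100 seeded random 200-nt sequences, both strands."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            s = "".join(rng.choice(list("ACGT"), size=200))
            hits = scan_rss(DnaSequence("r", s))
            assert hit_tuples(hits) == brute_force_scan(s)

    def test_oracle_equivalence_unanchored_and_loose(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=150, p=[0.2, 0.3, 0.3, 0.2]))
            hits = scan_rss(
                DnaSequence("r", s), params=ScanParams(4, 5, 1, anchor_cac=False)
            )
            got = brute_force_scan(s, (11, 12, 13, 22, 23, 24), 4, 5, False)
            assert hit_tuples(hits) == got

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), size=120))
            seq = DnaSequence("x", s)
            bottom = hit_tuples(scan_rss(seq, params=ScanParams(strands="bottom")))
            top_of_rc = hit_tuples(scan_rss(seq.revcomp("x"), params=ScanParams(strands="top")))
            assert {t[1:] for t in bottom} == {t[1:] for t in top_of_rc}

    def test_too_short_sequence_returns_empty(self):
        assert scan_rss(DnaSequence("s", "CACAGTGACAAAAACC")) == []

    @pytest.mark.parametrize("m_h,m_n,spacer", [(0, 0, 12), (2, 3, 23), (3, 4, 12)])
    def test_planted_hit_recovered(self, m_h, m_n, spacer):
        seq, truth = gen_rss_sequence(80, 25, m_h, spacer, m_n, seed=5)
        hits = scan_rss(seq, params=ScanParams(strands="top"))
        assert (
            "+",
            truth.params["heptamer_offset"],
            spacer,
            m_h,
            m_n,
        ) in hit_tuples(hits)

    def test_overbudget_planted_heptamer_absent(self):
        seq, _ = gen_rss_sequence(80, 25, 4, 12, 0, seed=6, anchor_cac=False)
        hits = scan_rss(seq, params=ScanParams(3, 4, 0, False, "top"))
        assert all(h.heptamer_start != 25 for h in hits)

    def test_deterministic_sort_order(self):
        seq, _ = gen_rss_sequence(200, 40, 1, 12, 1, seed=8)
        hits = scan_rss(seq)
        keys = [(h.mismatch_score, h.heptamer_start, h.strand != "+") for h in hits]
        assert keys == sorted(keys)


class TestMismatchScore:
    def test_perfect_consensus_scores_zero(self):
        assert mismatch_score(0, 0, 12) == 0.0

    def test_weighted_arithmetic(self):
        assert mismatch_score(2, 1, 12, weights=(2, 1, 1)) == 5.0
        assert mismatch_score(1, 1, 14, weights=(2, 1, 1)) == 5.0  # spacer dev 2

    def test_monotone_in_each_component(self):
        base = mismatch_score(1, 1, 12)
        assert mismatch_score(2, 1, 12) > base
        assert mismatch_score(1, 2, 12) > base
        assert mismatch_score(1, 1, 13) > base

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            mismatch_score(1, 1, 12, weights=(-1, 1, 1))


class TestModelScore:
    def test_uniform_model_scores_zero_everywhere(self):
        uniform = RSSModel(np.full((7, 4), 0.25), np.full((9, 4), 0.25))
        seq, _ = gen_rss_sequence(60, 17, 0, 12, 0, seed=3)
        for h in scan_rss(seq):
            assert model_score(h, uniform) == pytest.approx(0.0)

    def test_consensus_beats_any_single_mutant(self):
        model = RSSModel.default()
        best = model.score("CACAGTG", "ACAAAAACC", 12)
        for i in range(7):
            for b in "ACGT":
                if b == "CACAGTG"[i]:
                    continue
                mutant = "CACAGTG"[:i] + b + "CACAGTG"[i + 1:]
                assert model.score(mutant, "ACAAAAACC", 12) < best
        assert model.score("CACAGTG", "ACAAAAACC", 13) < best  # spacer penalty

    def test_canonical_substrate_outscores_cryptic_region(self, sequences):
        """Ordering sanity: the canonical 12RSS scores above the best cryptic
        arrangement of the RN7SKP123-MTF2 substrate under the default model."""
        model = RSSModel.default()
        akn1 = scan_rss(sequences["AKN1"], params=ScanParams(0, 0, strands="top"))[0]
        ap100 = scan_rss(sequences["AP100"], params=ScanParams(3, 4, 2, True, "top"))
        assert ap100, "cryptic region should yield at least one hit"
        best_cryptic = max(model_score(h, model) for h in ap100)
        assert model_score(akn1, model) > best_cryptic

    def test_json_round_trip(self, tmp_path):
        model = RSSModel.default()
        path = tmp_path / "model.json"
        model.to_json(path)
        again = RSSModel.from_json(path)
        assert again.score("CACAGTG", "ACAAAAACC", 12) == pytest.approx(
            model.score("CACAGTG", "ACAAAAACC", 12)
        )

    def test_invalid_frequency_table_rejected(self):
        bad = np.full((7, 4), 0.3)
        with pytest.raises(ValueError):
            RSSModel(bad, np.full((9, 4), 0.25))


class TestNickSite:
    def test_nick_falls_at_heptamer_start(self, sequences):
        hit = scan_rss(sequences["AKN1"], params=ScanParams(0, 0, strands="top"))[0]
        assert nick_site(hit) == 17  # length of the 5'-labelled fragment

    def test_no_flank_case(self):
        seq = DnaSequence("s", "CACAGTG" + "A" * 12 + "ACAAAAACC")
        hit = scan_rss(seq, params=ScanParams(0, 4, strands="top"))[0]
        assert nick_site(hit) == 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ScanParams(max_heptamer_mismatch=8)
    with pytest.raises(ValueError):
        ScanParams(spacer_tolerance=-1)
    with pytest.raises(ValueError):
        RSSConsensus(heptamer="CACA")
    with pytest.raises(ValueError):
        RSSConsensus(spacer_lengths=frozenset({0}))
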