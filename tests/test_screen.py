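import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_seq
from oracles import substring_levenshtein

from mirbact.formats import Alphabet, ReadPair, SequenceRecord, revcomp
from mirbact.screen import (
    CandidateSite,
    ScreenConfig,
    batch_fit_distances,
    fit_edit_distance,
    screen_read,
    screen_sample,
)


def _encode(text):
    return np.frombuffer(text.encode(), dtype=np.uint8)[None, :]


class TestFitEditDistance:
    def test_exact_substring_distance_zero_and_window(self):
        dist, window, trace = fit_edit_distance("ACGT", "TTACGTTT")
        assert dist == 0
        assert window == (2, 6)
        assert trace == "MMMM"

    def test_all_mismatch_pattern(self):
        dist, _, _ = fit_edit_distance("AAAA", "CCCCCC")
        assert dist == 4

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            fit_edit_distance("", "ACGT")

    def test_matches_substring_levenshtein_oracle(self, rng):
        for _ in range(200):
            pattern = random_seq(rng, int(rng.integers(15, 26)))
            text = random_seq(rng, 80)
            dist, (s, e), _ = fit_edit_distance(pattern, text)
            assert dist == substring_levenshtein(pattern, text)
            # window must realise the reported distance
            from oracles import levenshtein

            assert levenshtein(pattern, text[s:e]) == dist

    def test_batch_agrees_with_scalar(self, rng):
        pattern = random_seq(rng, 20)
        texts = np.vstack([_encode(random_seq(rng, 60)) for _ in range(50)])
        batch = batch_fit_distances(pattern, texts)
        for k in range(50):
            text = texts[k].tobytes().decode()
            assert batch[k] == fit_edit_distance(pattern, text)[0]

    def test_agrees_with_edlib_infix_mode(self, rng):
        import edlib

        for _ in range(300):
            pattern = random_seq(rng, int(rng.integers(10, 26)))
            text = random_seq(rng, int(rng.integers(30, 101)))
            ours = fit_edit_distance(pattern, text)[0]
            assert ours == edlib.align(pattern, text, mode="HW")["editDistance"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_tie_break_leftmost_then_shortest(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        pattern = random_seq(rng, int(rng.integers(4, 9)))
        text = random_seq(rng, 30)
        dist, (s, e), _ = fit_edit_distance(pattern, text)
        # no window with the same cost may start earlier, and no shorter
        # window with the same start may achieve the cost
        from oracles import levenshtein

        for s2 in range(s):
            for e2 in range(s2, len(text) + 1):
                assert levenshtein(pattern, text[s2:e2]) > dist or s2 >= s
        for e2 in range(s, e):
            assert levenshtein(pattern, text[s:e2]) > dist


class TestScreenRead:
    def test_exact_revcomp_site_found_with_zero_edits(self, mirna_22nt, rng):
        pattern = revcomp(mirna_22nt.as_dna().sequence)
        read = SequenceRecord(
            "r1", random_seq(rng, 30) + pattern + random_seq(rng, 30)
        )
        sites = screen_read(mirna_22nt, read)
        forward = [s for s in sites if s.orientation == "forward"]
        assert len(forward) == 1
        site = forward[0]
        assert site.edit_distance == 0
        assert site.start == 30 and site.end == 30 + 22
        assert site.target_rna == pattern.replace("T", "U")

    def test_mirna_identity_sequence_not_matched_by_default(self, mirna_22nt):
        # a read carrying the miRNA sequence itself does not hybridise
        read = SequenceRecord("r1", mirna_22nt.as_dna().sequence + "ACGTACGT" * 6)
        sites = screen_read(mirna_22nt, read)
        # the identity occurrence on the forward strand equals the revcomp
        # pattern on the reverse strand; exclude that orientation and
        # require no forward match
        assert all(s.edit_distance > 0 or s.orientation == "revcomp"
                   for s in sites)

    def test_identity_mode_finds_the_mirna_itself(self, mirna_22nt, rng):
        read = SequenceRecord(
            "r1", random_seq(rng, 20) + mirna_22nt.as_dna().sequence
            + random_seq(rng, 20)
        )
        cfg = ScreenConfig(pattern="identity")
        sites = screen_read(mirna_22nt, read, cfg)
        assert any(
            s.orientation == "forward" and s.edit_distance == 0 for s in sites
        )

    def test_four_edit_site_rejected_at_max_three(self, mirna_22nt, rng):
        pattern = revcomp(mirna_22nt.as_dna().sequence)
        # 4 substitutions spread over the site
        mutated = list(pattern)
        for pos in (2, 7, 12, 17):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        read = SequenceRecord("r1", "".join(mutated))
        assert screen_read(mirna_22nt, read) == []
        # but admitted once the budget covers it
        cfg = ScreenConfig(max_edits=4)
        assert any(s.edit_distance == 4 for s in screen_read(mirna_22nt, read, cfg))

    def test_orientation_complete(self, mirna_22nt, rng):
        pattern = revcomp(mirna_22nt.as_dna().sequence)
        read = SequenceRecord("r1", random_seq(rng, 25) + pattern
                              + random_seq(rng, 25))
        flipped = SequenceRecord("r1", revcomp(read.sequence))
        a = screen_read(mirna_22nt, read)
        b = screen_read(mirna_22nt, flipped)
        swap = {"forward": "revcomp", "revcomp": "forward"}
        key_a = {(s.orientation, s.edit_distance, s.target_rna) for s in a}
        key_b = {(swap[s.orientation], s.edit_distance, s.target_rna) for s in b}
        assert key_a == key_b

    def test_monotone_in_max_edits(self, mirna_22nt, rng):
        pattern = revcomp(mirna_22nt.as_dna().sequence)
        mutated = pattern[:5] + "A" + pattern[6:]
        read = SequenceRecord("r1", random_seq(rng, 10) + mutated
                              + random_seq(rng, 10))
        found = {}
        for max_edits in range(4):
            cfg = ScreenConfig(max_edits=max_edits)
            found[max_edits] = {
                (s.orientation, s.start, s.end)
                for s in screen_read(mirna_22nt, read, cfg)
            }
        for lo, hi in zip(range(3), range(1, 4)):
            assert found[lo] <= found[hi]


class TestScreenSample:
    def _pair(self, rng, mirna, pair_id="p1", both=True):
        pattern = revcomp(mirna.as_dna().sequence)
        m1 = random_seq(rng, 20) + pattern + random_seq(rng, 20)
        m2 = random_seq(rng, 20) + (pattern if both else random_seq(rng, 22)) \
            + random_seq(rng, 20)
        return ReadPair(
            pair_id,
            SequenceRecord(f"{pair_id}/1", m1),
            SequenceRecord(f"{pair_id}/2", m2),
            "S1",
        )

    def test_both_mates_counted_independently(self, mirna_22nt, rng):
        pair = self._pair(rng, mirna_22nt)
        sites = screen_sample([mirna_22nt], [pair])
        mates = {(s.mate, s.orientation) for s in sites}
        assert {(1, "forward"), (2, "forward")} <= mates

    def test_zero_pairs(self, mirna_22nt):
        assert screen_sample([mirna_22nt], []) == []

    def test_sorted_output(self, mirna_22nt, rng):
        pairs = [self._pair(rng, mirna_22nt, f"p{i}") for i in range(4)]
        sites = screen_sample([mirna_22nt], pairs)
        keys = [(s.mirna_id, s.read_id, s.mate) for s in sites]
        assert keys == sorted(keys)

    def test_planted_error_free_sites_all_recovered(self):
        from mirbact import synth
        from mirbact.screen import ScreenConfig

        mirnas = synth.simulate_mirnas(2, seed=9, length_range=(22, 22), gc=0.7)
        _t, genomes, _p, _o = synth.simulate_references(2, 5000, seed=9)
        genomes, planted = synth.plant_sites(
            genomes, mirnas, sites_per_taxon=2, edits=0, seed=9
        )
        pairs, truth = synth.simulate_read_pairs(
            genomes, {t: 1.0 for t in genomes}, 400, seed=9
        )
        sites = screen_sample(mirnas, pairs, ScreenConfig())
        # every mate fully covering a planted site must be recovered
        found = {(s.read_id, s.mirna_id) for s in sites}
        n_cover = 0
        for row in truth.itertuples():
            for mate, iv in ((1, (row.mate1_start, row.mate1_end)),
                             (2, (row.mate2_start, row.mate2_end))):
                for site in planted:
                    if site.taxon_id == row.taxon_id and \
                            iv[0] <= site.start and site.end <= iv[1]:
                        n_cover += 1
                        assert (f"{row.read_id}/{mate}", site.mirna_id) in found
        assert n_cover > 0  # the check must actually have exercised reads
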