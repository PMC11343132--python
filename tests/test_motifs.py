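"""Consensus matching, PWM scanning, sequence extraction, sampling, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosspeak.intervals import GenomicInterval, Peak, PeakSet
from crosspeak.motifs import (
    KB_CONSENSUS,
    Motif,
    enrichment_test,
    extract_peak_sequences,
    find_iupac_hits,
    match_iupac,
    random_regions,
    reverse_complement,
    sample_peaks,
    scan_pwm,
)
from oracles import hypergeom_upper_tail, iupac_hits_bruteforce, pwm_hits_bruteforce


def peak(chrom, start, end, pid):
    return Peak(GenomicInterval(chrom, start, end), pid, 10.0, 0.001)


class TestIupac:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGACTTTCC", True),  # R<-A, N<-C, optional Y<-T
            ("GGAAAGTCCC", True),  # minus strand (revcomp is GGGACTTTCC)
            ("GGGACTTTCA", False),  # final C violated
            ("GGGACTTCC", True),  # 9-mer with the optional position skipped
            ("GGGACTTTNC", False),  # subject N never matches a constrained position
            ("ATATATATATAT", False),
        ],
    )
    def test_consensus_examples(self, seq, expected):
        assert match_iupac(seq, KB_CONSENSUS) is expected

    def test_invalid_iupac_letter_rejected_at_load(self):
        with pytest.raises(ValueError):
            Motif(name="bad", iupac="GGGQ")
        with pytest.raises(ValueError):
            Motif(name="too_optional", iupac="(A)(C)(G)T")

    def test_hit_positions_recorded_on_forward_coordinates(self):
        seq = "TT" + "GGGACTTTCC" + "AAA"
        hits = find_iupac_hits(seq, KB_CONSENSUS)
        assert any(h.start == 2 and h.width == 10 and h.strand == "+" for h in hits)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    def test_strand_symmetry(self, seq):
        assert match_iupac(seq, KB_CONSENSUS) == match_iupac(
            reverse_complement(seq), KB_CONSENSUS
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_hits_match_bruteforce_scanner(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=120, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        # plant one consensus occurrence half the time
        if rng.random() < 0.5:
            pos = int(rng.integers(0, 110))
            seq = seq[:pos] + "GGGACTTTCC" + seq[pos + 10 :]
        got = {(h.start, h.width, h.strand) for h in find_iupac_hits(seq, KB_CONSENSUS)}
        expected = iupac_hits_bruteforce(seq, KB_CONSENSUS._variants)
        assert got == expected


class TestPwm:
    def _sharp_pwm(self, consensus):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        pwm = np.full((4, len(consensus)), 0.01)
        for j, b in enumerate(consensus):
            pwm[idx[b], j] = 0.97
        return pwm

    def test_planted_consensus_is_argmax(self):
        consensus = "GGGACTTTCC"
        pwm = self._sharp_pwm(consensus)
        motif = Motif(name="m", pwm=pwm, llr_threshold=-1e9)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:90] + consensus + seq[100:]
        hits = scan_pwm(seq, motif)
        best = max(hits, key=lambda h: h.score)
        assert best.start == 90 and best.strand == "+"

    def test_uniform_pwm_scores_zero_everywhere(self):
        motif = Motif(name="u", pwm=np.full((4, 6), 0.25), llr_threshold=0.0)
        hits = scan_pwm("ACGTACGTACGT", motif)
        assert hits and all(h.score == pytest.approx(0.0) for h in hits)

    def test_pwm_columns_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Motif(name="bad", pwm=np.full((4, 5), 0.3), llr_threshold=1.0)

    def test_hits_match_bruteforce(self):
        rng = np.random.default_rng(11)
        pwm = self._sharp_pwm("GGGACTTTCC")
        motif = Motif(name="m", pwm=pwm, llr_threshold=6.0)
        seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        seq = seq[:50] + "GGGACTTTCC" + seq[60:]
        seq = seq[:150] + "GGAAAGTCCC" + seq[160:]
        got = [(h.start, h.strand, h.score) for h in scan_pwm(seq, motif)]
        expected = pwm_hits_bruteforce(seq, pwm, 6.0)
        assert len(got) == len(expected)
        for (gs, gst, gsc), (es, est, esc) in zip(
            sorted(got), sorted(expected, key=lambda t: (t[0], t[1]))
        ):
            assert (gs, gst) == (es, est)
            assert gsc == pytest.approx(esc)


class TestExtraction:
    def test_padding_clipped_at_chromosome_edge(self):
        genome = {"c": "ACGTACGTAC"}
        seqs = extract_peak_sequences(PeakSet("s", [peak("c", 0, 10, "p")]), genome, pad=5)
        assert seqs["p"] == "ACGTACGTAC"  # left and right clip
        seqs = extract_peak_sequences(PeakSet("s", [peak("c", 2, 6, "p")]), genome, pad=2)
        assert len(seqs["p"]) == 8

    def test_zero_pad_lengths_match_intervals(self, small_bundle):
        ps = small_bundle.level_sets[0]
        seqs = extract_peak_sequences(ps, small_bundle.genome)
        for p in ps:
            assert len(seqs[p.peak_id]) == p.interval.length

    def test_unknown_chromosome_lists_offenders(self):
        with pytest.raises(KeyError, match="chrMissing"):
            extract_peak_sequences(
                PeakSet("s", [peak("chrMissing", 0, 10, "p")]), {"c": "ACGT" * 5}
            )

    def test_planted_motifs_recoverable_at_recorded_offsets(self, small_bundle):
        truth = small_bundle.truth_peaks
        embedded = truth[(truth.set_label == "level0") & truth.motif_embedded]
        assert len(embedded) > 0
        for row in embedded.itertuples():
            site_seq = small_bundle.genome[row.chrom][row.embedded_offset : row.embedded_offset + 10]
            assert match_iupac(site_seq, KB_CONSENSUS)


class TestSampling:
    def _ps(self, n):
        return PeakSet("s", [peak("c", 100 * i, 100 * i + 50, f"p{i}") for i in range(n)])

    def test_small_set_returned_whole(self):
        ps = self._ps(400)
        assert sample_peaks(ps, n=1000, seed=1).ids == ps.ids

    def test_same_seed_same_sample(self):
        ps = self._ps(50)
        assert sample_peaks(ps, 10, seed=42).ids == sample_peaks(ps, 10, seed=42).ids
        assert sample_peaks(ps, 10, seed=42).ids != sample_peaks(ps, 10, seed=43).ids

    def test_single_draw_frequencies_are_uniform(self):
        ps = self._ps(10)
        counts = {pid: 0 for pid in ps.ids}
        for i in range(10_000):
            counts[sample_peaks(ps, 1, seed=i).ids[0]] += 1
        # 99.9% binomial CI around p = 0.1
        half_width = 3.29 * np.sqrt(0.1 * 0.9 / 10_000)
        for pid, c in counts.items():
            assert abs(c / 10_000 - 0.1) < half_width

    def test_random_regions_avoid_excluded_peaks(self):
        exclude = PeakSet("e", [peak("c", 0, 5_000, "big")])
        bg = random_regions({"c": 10_000}, n=20, width=100, seed=3, exclude=[exclude])
        for p in bg:
            assert p.interval.start >= 5_000


class TestEnrichment:
    def _genome_with_plants(self, n_target, k_target, n_background, k_background):
        width = 50
        total = n_target + n_background
        rng = np.random.default_rng(99)
        # AT-rich background so chance consensus matches are essentially absent
        seq = list("".join(rng.choice(list("AT"), size=total * 100)))
        target, background = [], []
        for i in range(total):
            start = i * 100 + 20
            planted = (i < k_target) if i < n_target else (i - n_target < k_background)
            if planted:
                seq[start + 20 : start + 30] = list("GGGACTTTCC")
            p = peak("c", start, start + width, f"{'t' if i < n_target else 'b'}{i}")
            (target if i < n_target else background).append(p)
        genome = {"c": "".join(seq)}
        return PeakSet("t", target), PeakSet("b", background), genome

    def test_zero_target_hits_gives_p_of_one(self):
        t, b, genome = self._genome_with_plants(10, 0, 50, 5)
        res = enrichment_test(t, b, KB_CONSENSUS, genome)
        assert res.k_target == 0 and res.p_value == pytest.approx(1.0)

    def test_p_matches_pmf_enumeration(self):
        t, b, genome = self._genome_with_plants(10, 5, 100, 10)
        res = enrichment_test(t, b, KB_CONSENSUS, genome)
        assert (res.k_target, res.k_background) == (5, 10)
        expected = hypergeom_upper_tail(5, 110, 15, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.neg_log10_p == pytest.approx(-np.log10(expected), rel=1e-9)

    def test_equal_proportions_are_not_enriched(self):
        t, b, genome = self._genome_with_plants(50, 10, 50, 10)
        res = enrichment_test(t, b, KB_CONSENSUS, genome)
        assert res.p_value >= 0.4

    def test_p_monotone_decreasing_in_target_hits(self):
        # fixed margins: 20 target, 80 background, 20 total hits
        ps = []
        for k_t in (4, 8, 12):
            t, b, genome = self._genome_with_plants(20, k_t, 80, 20 - k_t)
            ps.append(enrichment_test(t, b, KB_CONSENSUS, genome).p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_overlapping_id_spaces_rejected(self):
        t, b, genome = self._genome_with_plants(5, 2, 10, 2)
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_test(t, t, KB_CONSENSUS, genome)

    def test_empty_target_rejected(self):
        t, b, genome = self._genome_with_plants(5, 2, 10, 2)
        with pytest.raises(ValueError, match="empty"):
            enrichment_test(PeakSet("x", []), b, KB_CONSENSUS, genome)
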