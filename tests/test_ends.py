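"""Poly(A) detection, primary stops, positional codon counts, depletion."""

import numpy as np
import pytest

from ambicode.codes import CODONS, TranscriptRecord
from ambicode.ends import (
    DEFAULT_STOP_SET,
    PolyACall,
    base_frequency_profile,
    detect_polya,
    find_primary_stop,
    positional_codon_counts,
    primary_stops_from_annotation,
    stop_depletion_test,
    utr_length_distribution,
)
from ambicode.simulate import SimConfig, simulate_transcriptome


class TestDetectPolya:
    def test_clean_tail_at_junction(self):
        seq = "CCGGTTGCT" + "A" * 8
        call = detect_polya(seq)
        assert call.polya_site == 9
        assert call.tail_length == 8

    def test_below_min_tail_absent(self):
        assert detect_polya("CCGGTTGCT" + "A" * 7, min_tail=8) is None

    def test_one_internal_mismatch_allowed(self):
        seq = "CCGGTTGCT" + "AAAA" + "G" + "AAAA"
        call = detect_polya(seq, min_tail=8, max_mismatch=1)
        assert call.polya_site == 9
        call0 = detect_polya(seq, min_tail=8, max_mismatch=0)
        assert call0 is None  # only the terminal 4-mer remains

    def test_simulated_sites_recovered_exactly_when_unambiguous(self):
        """Simulated tails are mismatch-free; every transcript whose 3'UTR
        keeps >= 2 templated non-A bases at the junction is recovered at the
        exact ground-truth position."""
        cfg = SimConfig(seed=3, n_transcripts=500)
        trs, truth = simulate_transcriptome(cfg)
        checked = 0
        for tr, polya, utr in zip(trs, truth.polya_site, truth.utr_length):
            call = detect_polya(tr.seq, transcript_id=tr.id)
            assert call is not None
            if utr >= 2:
                checked += 1
                assert call.polya_site == polya
        assert checked > 400


class TestFindPrimaryStop:
    def _tr(self, seq, cds_start=0, cds_end=None):
        return TranscriptRecord("t", seq, cds_start=cds_start, cds_end=cds_end)

    def test_stop_immediately_before_tail_gives_zero_utr(self):
        seq = "ATGCCTGGG" + "TAA" + "A" * 20
        tr = self._tr(seq, 0, 12)
        call = find_primary_stop(tr, detect_polya(seq), stop_set=DEFAULT_STOP_SET)
        assert call.stop_codon == "TAA"
        assert call.utr_length == 0

    def test_utr_of_21_nt(self):
        utr = "TCTCTCTCTCTCTCTCTCTCT"  # 21 nt, no A
        seq = "ATGCCTGGG" + "TGA" + utr + "A" * 20
        tr = self._tr(seq, 0, 12)
        call = find_primary_stop(tr, detect_polya(seq), stop_set=DEFAULT_STOP_SET)
        assert call.stop_start == 9
        assert call.utr_length == 21

    def test_most_5prime_stop_wins_and_downstream_reported(self):
        seq = "ATGCCTGGG" + "TGA" + "TCT" + "TAA" + "TCTCT" + "A" * 20
        tr = self._tr(seq, 0, 12)
        call = find_primary_stop(tr, detect_polya(seq), stop_set=DEFAULT_STOP_SET)
        assert call.stop_codon == "TGA"
        assert call.downstream_stops == [15]

    def test_unknown_frame_raises(self):
        tr = TranscriptRecord("t", "ATGTAA" + "A" * 10)
        with pytest.raises(ValueError, match="frame"):
            find_primary_stop(tr, PolyACall("t", 6, 10))

    def test_insensitive_to_sequence_downstream_of_tail(self):
        base = "ATGCCTGGG" + "TGA" + "TCT"
        a, b = base + "A" * 12, base + "A" * 12 + "GGGCCC"
        polya = PolyACall("t", 15, 12)
        ca = find_primary_stop(self._tr(a, 0, 12), polya)
        cb = find_primary_stop(self._tr(b, 0, 12), polya)
        assert (ca.stop_start, ca.utr_length) == (cb.stop_start, cb.utr_length)

    def test_simulated_standard_code_cohort_fully_recovered(self):
        """Without sense 'stop' codons, every in-window simulated stop is
        called at its true position."""
        cfg = SimConfig(seed=9, n_transcripts=1000, code="standard")
        trs, truth = simulate_transcriptome(cfg)
        n = 0
        for tr, stop_start in zip(trs, truth.stop_start):
            call = find_primary_stop(
                tr, detect_polya(tr.seq, transcript_id=tr.id), stop_set=DEFAULT_STOP_SET
            )
            assert call is not None
            assert call.stop_start == stop_start
            n += 1
        assert n == 1000


class TestUtrDistribution:
    def _calls(self, lengths):
        from ambicode.ends import PrimaryStopCall

        return [PrimaryStopCall(f"t{i}", "TAA", 0, l) for i, l in enumerate(lengths)]

    def test_median_of_three(self):
        s = utr_length_distribution(self._calls([0, 21, 23]))
        assert s.median == 21

    def test_all_zero(self):
        s = utr_length_distribution(self._calls([0, 0, 0]))
        assert s.median == 0
        assert s.fraction_zero == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            utr_length_distribution([])

    def test_histogram_at_single_nt_resolution(self):
        s = utr_length_distribution(self._calls([0, 1, 1, 5]))
        assert s.histogram == {0: 1, 1: 2, 5: 1}


class TestPositionalCodonCounts:
    def test_tail_completion_of_terminal_dinucleotide(self):
        # transcript ends ...TA + tail: final codon completes to TAA
        seq = "ATGCCTGGGTA" + "A" * 12
        tr = TranscriptRecord("t", seq, frame=0, cds_start=0)
        counts = positional_codon_counts([(tr, PolyACall("t", 11, 12))], window=12)
        assert counts.counts.loc[-3, "TAA"] == 1
        assert counts.tail_completion_used == {1: 1}

    def test_nine_nt_gives_three_codons(self):
        seq = "ATGCCTGGG" + "A" * 12
        tr = TranscriptRecord("t", seq, frame=0, cds_start=0)
        counts = positional_codon_counts([(tr, PolyACall("t", 9, 12))], window=240)
        assert counts.total_by_bin().loc[[-3, -6, -9]].tolist() == [1, 1, 1]
        assert counts.counts.loc[-3, "GGG"] == 1
        assert counts.counts.loc[-9, "ATG"] == 1

    def test_matches_string_walk_oracle(self, small_cohort):
        """Simulated cohort: counts equal an independent per-transcript walk."""
        _, trs, truth = small_cohort
        pairs = [
            (tr, PolyACall(tr.id, p, t))
            for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)
        ]
        counts = positional_codon_counts(pairs, window=240)
        oracle = {}
        for tr, polya in pairs:
            p = polya.polya_site
            span = p - tr.cds_start
            borrow = (3 - span % 3) % 3
            # complete the final codon with tail As, then step back in frame
            padded = tr.seq[: p] + "A" * borrow
            end = p + borrow
            d = -3
            while end - 3 >= tr.cds_start and -d <= 240:
                codon = padded[end - 3 : end]
                oracle[(d, codon)] = oracle.get((d, codon), 0) + 1
                end -= 3
                d -= 3
        for (d, codon), n in oracle.items():
            assert counts.counts.loc[d, codon] == n
        assert counts.counts.to_numpy().sum() == sum(oracle.values())

    def test_conservation_of_total_codons(self, small_cohort):
        _, trs, truth = small_cohort
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        counts = positional_codon_counts(pairs, window=300)
        expected = 0
        for tr, polya in pairs:
            covered = polya.polya_site - tr.cds_start
            expected += min((covered + 2) // 3, 100)
        assert counts.counts.to_numpy().sum() == expected


class TestDepletion:
    def test_zero_proximal_gives_zero_ratio(self, small_cohort):
        _, trs, truth = small_cohort
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        counts = positional_codon_counts(pairs, window=480)
        counts.counts.loc[
            (counts.counts.index >= -90) & (counts.counts.index < -42), "TGA"
        ] = 0
        rep = stop_depletion_test(counts, "TGA")
        assert rep.ratio == 0.0
        assert rep.proximal_count == 0

    def test_disjoint_ranges_enforced(self, small_cohort):
        _, trs, truth = small_cohort
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        counts = positional_codon_counts(pairs, window=480)
        with pytest.raises(ValueError):
            stop_depletion_test(counts, "TGA", proximal=(-300, -200), distal=(-250, -100))

    def test_depleted_cohort_flagged_only_for_stop_set(self):
        cfg = SimConfig(seed=21, n_transcripts=1200, code="ambiguous-cmag", depletion_factor=0.3)
        trs, truth = simulate_transcriptome(cfg)
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        counts = positional_codon_counts(pairs, window=480)
        for codon in ("TAA", "TAG", "TGA"):
            rep = stop_depletion_test(counts, codon)
            assert rep.ratio < 1
            assert rep.p_value < 1e-2
        for codon in ("GCT", "AAA", "TTT", "CAT"):
            rep = stop_depletion_test(counts, codon)
            assert not (rep.ratio < 0.8 and rep.p_value < 1e-3)


class TestBaseFrequencyProfile:
    def test_all_a_input(self):
        tr = TranscriptRecord("t", "A" * 60, frame=0)
        prof = base_frequency_profile([(tr, PolyACall("t", 50, 10))], window=30)
        assert np.allclose(prof.frequencies["A"].dropna(), 1.0)

    def test_matches_column_tally(self, small_cohort):
        _, trs, truth = small_cohort
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        prof = base_frequency_profile(pairs, window=60)
        # independent tally at a handful of offsets
        for off in (-1, -17, -60):
            col = [tr.seq[polya.polya_site + off] for tr, polya in pairs if polya.polya_site + off >= 0]
            for b in "ACGT":
                assert prof.frequencies.loc[off, b] == pytest.approx(
                    sum(1 for x in col if x == b) / len(col)
                )

    def test_uniform_composition_is_flat(self):
        cfg = SimConfig(seed=13, n_transcripts=800, code="standard")
        trs, truth = simulate_transcriptome(cfg)
        pairs = [(tr, PolyACall(tr.id, p, t)) for tr, p, t in zip(trs, truth.polya_site, truth.tail_length)]
        prof = base_frequency_profile(pairs, window=240, stable_region=(-90, -42))
        # CDS composition is positionally exchangeable: deviations in the
        # stable region stay within ~3 binomial standard errors
        n = prof.coverage.loc[-60]
        for b in "ACGT":
            region = prof.frequencies.loc[-90:-43, b]
            se = np.sqrt(region.mean() * (1 - region.mean()) / n)
            assert prof.flatness[b] < 4 * se


def test_primary_stops_from_annotation(small_cohort):
    _, trs, truth = small_cohort
    for tr, p in zip(trs, truth.polya_site):
        tr.polya_site = p
    calls = primary_stops_from_annotation(trs)
    assert [c.stop_codon for c in calls] == truth.stop_codon
    assert [c.utr_length for c in calls] == truth.utr_length
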