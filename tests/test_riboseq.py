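"""Footprint filtering, metaprofiles, termination, readthrough."""

import numpy as np
import pytest

from ambicode.codes import TranscriptRecord
from ambicode.ends import PrimaryStopCall
from ambicode.riboseq import (
    MetaProfile,
    RPFRecord,
    classify_termination,
    coverage_track,
    end_metaprofile,
    estimate_readthrough,
    filter_rpfs,
    frame_distribution,
    readthrough_density_ratio,
)
from ambicode.simulate import (
    SimConfig,
    simulate_rpfs,
    simulate_transcriptome,
    write_sam,
)


@pytest.fixture(scope="module")
def rpf_cohort():
    cfg = SimConfig(seed=17, n_transcripts=150, code="ambiguous-cmag", readthrough_rate=0.02)
    trs, truth = simulate_transcriptome(cfg)
    reads = simulate_rpfs(cfg, truth, trs)
    return cfg, trs, truth, reads


class TestFilterRpfs:
    def test_length_and_mismatch_bounds(self, tmp_path, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        sam = tmp_path / "reads.sam"
        write_sam(reads, trs, sam)
        kept, report = filter_rpfs(sam)
        # independent predicate scan over the simulated reads
        expected = [r for r in reads if 25 <= r.length <= 32 and r.mismatches <= 1]
        assert report.n_input == len(reads)
        assert len(kept) == len(expected)
        assert sorted(k.read_id for k in kept) == sorted(r.read_id for r in expected)

    def test_out_of_range_lengths_rejected(self, tmp_path, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        sam = tmp_path / "narrow.sam"
        write_sam(reads, trs, sam)
        kept, report = filter_rpfs(sam, len_min=30, len_max=30)
        assert all(k.length == 30 for k in kept)
        assert report.rejects["length"] == sum(1 for r in reads if r.length != 30)

    def test_mismatches_recomputed_without_nm_tag(self, tmp_path):
        import pysam

        ref = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        tr = TranscriptRecord("t0", ref)
        path = tmp_path / "nonm.sam"
        with pysam.AlignmentFile(
            str(path), "wh", header={"HD": {"VN": "1.6"}, "SQ": [{"SN": "t0", "LN": len(ref)}]}
        ) as out:
            a = pysam.AlignedSegment()
            a.query_name = "r0"
            a.query_sequence = "C" + ref[1:29]  # one substitution at position 0
            a.flag = 0
            a.reference_id = 0
            a.reference_start = 0
            a.mapping_quality = 255
            a.cigarstring = "29M"
            out.write(a)
        kept, _ = filter_rpfs(path, references={"t0": ref})
        assert len(kept) == 1
        assert kept[0].mismatches == 1


class TestFrameDistribution:
    def test_recovers_simulated_frame_bias(self, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        elong = [r.as_record() for r in reads if r.true_class == "elongating"]
        df = frame_distribution(elong, {tr.id: tr for tr in trs})
        pooled = (df["end3_frame3"] * df["n"]).sum() / df["n"].sum()
        n = df["n"].sum()
        se = np.sqrt(cfg.frame3_bias * (1 - cfg.frame3_bias) / n)
        assert abs(pooled - cfg.frame3_bias) < 5 * se

    def test_fractions_sum_to_one(self, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        df = frame_distribution([r.as_record() for r in reads], {tr.id: tr for tr in trs})
        for name in ("start5", "end3"):
            sums = df[[f"{name}_frame{k}" for k in (1, 2, 3)]].sum(axis=1)
            assert np.allclose(sums, 1.0)


class TestMetaprofile:
    def test_single_end_offset_convention(self):
        # stop codon at 100..102; read ends 11 nt after the stop 3' nt (102)
        read = RPFRecord("r", "t", 84, 114, 30)
        prof = end_metaprofile([read], [("t", 100)], flank=30)
        assert prof.total == 1
        assert prof.as_series().loc[14] == 1  # anchor codon = positions 1-3

    def test_empty_profile(self):
        prof = end_metaprofile([], [("t", 100)])
        assert prof.total == 0

    def test_matches_per_anchor_tally(self, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        rpfs = [r.as_record() for r in reads]
        anchors = list(zip(truth.transcript_ids, truth.stop_start))[:50]
        prof = end_metaprofile(rpfs, anchors, flank=20)
        oracle = {}
        for tid, s in anchors:
            for r in rpfs:
                if r.transcript_id != tid:
                    continue
                off = (r.end - 1) - s + 1
                if -20 <= off <= 23:
                    oracle[off] = oracle.get(off, 0) + 1
        assert dict(zip(prof.offsets[prof.counts > 0], prof.counts[prof.counts > 0])) == oracle

    def test_out_of_bounds_anchor_skipped(self):
        prof = end_metaprofile([], [("t", -5)])
        assert prof.n_skipped_anchors == 1


class TestClassifyTermination:
    def _profile(self, end_offsets_rel_stop3):
        offsets = np.arange(-30, 34)
        counts = np.zeros(len(offsets), dtype=np.int64)
        for o in end_offsets_rel_stop3:
            counts[o + 3 + 30] += 1  # profile offset = rel + 3
        return MetaProfile(offsets, counts, "terminating-stop", 1)

    def test_all_ends_at_plus_eleven(self):
        rep = classify_termination(self._profile([11] * 40))
        assert rep.modal_offsets == (11,)
        assert rep.fraction_in_modal == 1.0

    def test_signature_recovery(self):
        rep = classify_termination(self._profile([11] * 45 + [12] * 45 + [-5] * 10))
        assert rep.modal_offsets == (11, 12)
        assert rep.fraction_in_modal == pytest.approx(0.9)
        assert rep.has_signature

    def test_uniform_ends_no_signature(self, rng):
        rep = classify_termination(self._profile(list(rng.integers(-20, 25, size=500))))
        assert not rep.has_signature

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_termination(self._profile([]))


class TestReadthrough:
    def _calls(self, truth):
        return [
            PrimaryStopCall(tid, codon, s, u)
            for tid, codon, s, u in zip(
                truth.transcript_ids, truth.stop_codon, truth.stop_start, truth.utr_length
            )
        ]

    def test_no_downstream_gives_zero(self):
        rpfs = [RPFRecord(f"r{i}", "t", 80, 113, 33 - 0) for i in range(100)]
        # all ends at stop3 + 11 (stop at 100..102)
        rpfs = [RPFRecord(f"r{i}", "t", 84, 114, 30) for i in range(100)]
        est, summ = estimate_readthrough(rpfs, [PrimaryStopCall("t", "TAA", 100, 5)])
        assert est[0].rate == 0.0
        assert est[0].covered
        assert summ.fraction_zero == 1.0

    def test_rate_recovery_at_two_percent(self, rpf_cohort):
        cfg, trs, truth, reads = rpf_cohort
        est, summ = estimate_readthrough([r.as_record() for r in reads], self._calls(truth))
        assert summ.n_covered > 100
        assert abs(summ.mean_rate - 0.02) < 0.01

    def test_majority_zero_distribution_shape(self):
        cfg = SimConfig(
            seed=23, n_transcripts=300, code="ambiguous-cmag",
            readthrough_rate=0.1, readthrough_zero_fraction=0.9,
        )
        trs, truth = simulate_transcriptome(cfg)
        reads = simulate_rpfs(cfg, truth, trs)
        est, summ = estimate_readthrough([r.as_record() for r in reads], self._calls(truth))
        assert summ.median_rate == 0.0
        assert abs(summ.fraction_zero - 0.9) < 0.06

    def test_density_ratio_alternative(self):
        rpfs = [RPFRecord(f"r{i}", "t", 84, 114, 30) for i in range(30)]
        rpfs += [RPFRecord(f"d{i}", "t", 90, 120, 30) for i in range(3)]
        ratio = readthrough_density_ratio(rpfs, PrimaryStopCall("t", "TAA", 100, 5))
        assert ratio == pytest.approx(0.1)


class TestCoverage:
    def test_single_read(self):
        cov = coverage_track([RPFRecord("r", "t", 10, 40, 30)], 60)
        assert cov.sum() == 30
        assert cov[10] == 1 and cov[39] == 1 and cov[40] == 0

    def test_overlap_plateau(self):
        cov = coverage_track(
            [RPFRecord("a", "t", 0, 30, 30), RPFRecord("b", "t", 20, 50, 30)], 60
        )
        assert (cov[20:30] == 2).all()
        assert (cov[0:20] == 1).all()

    def test_matches_interval_stabbing(self, rng):
        reads = [
            RPFRecord(f"r{i}", "t", int(s), int(s) + 28, 28)
            for i, s in enumerate(rng.integers(0, 150, size=200))
        ]
        cov = coverage_track(reads, 200)
        for p in rng.integers(0, 200, size=25):
            assert cov[p] == sum(1 for r in reads if r.start <= p < r.end)

    def test_translated_upstream_sense_stops_show_no_coverage_drop(self):
        """In-frame sense 'stop' codons upstream of the true stop are fully
        translated: their footprint coverage matches flanking codons."""
        cfg = SimConfig(seed=29, n_transcripts=400, code="ambiguous-cmag")
        trs, truth = simulate_transcriptome(cfg)
        reads = simulate_rpfs(cfg, truth, trs)
        by_tr = {}
        for r in reads:
            by_tr.setdefault(r.transcript_id, []).append(r.as_record())
        term = {"TAA", "TAG", "TGA"}
        ratios = []
        for tr in trs:
            body = tr.seq[tr.cds_start + 3 : tr.cds_end - 3]
            for k in range(0, len(body) // 3):
                codon_start = tr.cds_start + 3 + 3 * k
                if (
                    body[3 * k : 3 * k + 3] in term
                    and tr.cds_end - 3 - codon_start > 60
                    and codon_start >= 15
                ):
                    cov = coverage_track(by_tr.get(tr.id, []), tr)
                    here = cov[codon_start : codon_start + 3].mean()
                    flank = cov[codon_start - 15 : codon_start + 18].mean()
                    if flank > 0:
                        ratios.append(here / flank)
        assert len(ratios) > 20
        assert abs(np.mean(ratios) - 1.0) < 0.1
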