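"""Read filtering, cargo location, flank typing and insertion calling."""

import numpy as np
import pytest

from castworks import profiler, simgen
from castworks.align import KmerIndex, LocalAligner
from castworks.dna import random_dna, revcomp
from castworks.profiler import ReadRecord
from castworks.simgen.genome import SimGenome, Target
from oracles import binomial_ci


def _read(seq, q=30, rid="r"):
    return ReadRecord(rid, seq, q)


class TestFilterReads:
    def test_length_and_quality_rules(self):
        rng = np.random.default_rng(0)
        reads = [
            _read(random_dna(rng, 140), q=30, rid="short"),
            _read(random_dna(rng, 9000), q=30, rid="mid"),
            _read(random_dna(rng, 12_000), q=15, rid="lowq"),
            _read(random_dna(rng, 12_000), q=30, rid="good"),
        ]
        flt = profiler.filter_reads(reads)
        assert [r.id for r in flt.qc_set] == ["mid", "good"]
        assert [r.id for r in flt.analysis_set] == ["good"]
        assert dict(flt.rejected) == {"short": "short", "lowq": "low_quality"}

    def test_toy_fastq_hand_count(self, tmp_path, scenario):
        """5 low-quality + 5 short + 10 long clean reads -> 10 in the
        analysis set (hand-counted fixture)."""
        g, truth, v = scenario["genome"], scenario["truth"], scenario["vector"]
        long_clean, _ = simgen.simulate_long_reads(
            g, truth, v, 10, length_dist=("point", 12_000),
            per_base_error=0, mean_quality=30, seed=1)
        low_q, _ = simgen.simulate_long_reads(
            g, truth, v, 5, length_dist=("point", 12_000),
            per_base_error=0, mean_quality=10, seed=2)
        rng = np.random.default_rng(3)
        short = [simgen.SimRead(f"s{i}", random_dna(rng, 100),
                                np.full(100, 30)) for i in range(5)]
        path = tmp_path / "toy.fastq"
        simgen.write_fastq(long_clean + low_q + short, path)
        flt = profiler.filter_reads(path)
        assert flt.n_input == 20
        assert len(flt.analysis_set) == 10

    def test_malformed_fastq_record_rejected_per_record(self, tmp_path):
        good = "@ok\nACGTACGTAC\n+\n!!!!!!!!!!\n"
        bad = "@broken\nACGT\n+\n!!!\n"  # length mismatch
        p = tmp_path / "mixed.fastq"
        p.write_text(bad + good)
        reads, rejected = profiler.parse_fastq(p)
        assert [r.id for r in reads] == ["ok"]
        assert rejected[0][0] == "broken"

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            profiler.filter_reads([], min_quality=0)


class TestLocateCargo:
    def test_error_free_spanning_read_covers_right_end_fully(self, scenario):
        tn = scenario["transposon"]
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 500) + tn.seq + random_dna(rng, 500)
        hit = profiler.locate_cargo(_read(seq), tn)
        assert hit.right_end_coverage == 1.0
        assert hit.left_end_found
        assert (hit.q_start, hit.q_end) == (500, 500 + len(tn.seq))

    def test_read_covering_70pct_of_right_end_rejected(self, scenario):
        tn = scenario["transposon"]
        re_len = tn.right_end[1] - tn.right_end[0]
        cut = tn.right_end[0] + int(0.7 * re_len)
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 400) + tn.seq[:cut]
        assert profiler.locate_cargo(_read(seq), tn) == \
            "right_end_below_threshold"

    def test_read_without_cargo_rejected(self, scenario):
        rng = np.random.default_rng(3)
        assert profiler.locate_cargo(_read(random_dna(rng, 2000)),
                                     scenario["transposon"]) == "no_cargo"


@pytest.fixture(scope="module")
def indexes(scenario):
    al = LocalAligner()
    return (KmerIndex(scenario["genome"].sequence, al.word_size),
            KmerIndex(scenario["vector"].seq, al.word_size), al)


class TestClassifyFlanks:
    def _hit_and_read(self, scenario, cointegrate, flank=600):
        g, t, v = scenario["genome"], scenario["target"], scenario["vector"]
        ins = simgen.inserted_sequence(v, "RL", t.strand, cointegrate)
        p = t.junction_at(49)
        seq = g.sequence[p - flank:p] + ins + g.sequence[p:p + flank]
        read = _read(seq)
        hit = profiler.locate_cargo(read, scenario["transposon"])
        return read, hit

    def test_simple_insertion_has_two_genomic_flanks(self, scenario, indexes):
        gi, pi, al = indexes
        read, hit = self._hit_and_read(scenario, cointegrate=False)
        fl = profiler.classify_flanks(read, hit, gi, pi, al)
        assert (fl.left_flank, fl.right_flank) == ("genomic", "genomic")

    def test_cointegrate_read_has_plasmid_involved_flank(self, scenario,
                                                         indexes):
        gi, pi, al = indexes
        read, hit = self._hit_and_read(scenario, cointegrate=True)
        fl = profiler.classify_flanks(read, hit, gi, pi, al)
        assert "plasmid" in (fl.left_flank, fl.right_flank) or \
            "both" in (fl.left_flank, fl.right_flank)

    def test_90bp_genomic_flank_is_unmapped(self, scenario, indexes):
        gi, pi, al = indexes
        read, hit = self._hit_and_read(scenario, cointegrate=False, flank=90)
        fl = profiler.classify_flanks(read, hit, gi, pi, al,
                                      min_flank_bp=100)
        assert fl.left_flank == "unmapped"
        assert fl.left_mapped["genome"] <= 100


class TestCallInsertion:
    def _call(self, scenario, orientation, offset, cointegrate=False,
              window=100, symmetric=False):
        g, t, v = scenario["genome"], scenario["target"], scenario["vector"]
        al = LocalAligner()
        gi = KmerIndex(g.sequence, al.word_size)
        pi = KmerIndex(v.seq, al.word_size)
        ins = simgen.inserted_sequence(v, orientation, t.strand, cointegrate)
        p = t.junction_at(offset)
        seq = g.sequence[p - 700:p] + ins + g.sequence[p:p + 700]
        read = _read(seq)
        hit = profiler.locate_cargo(read, scenario["transposon"], al)
        fl = profiler.classify_flanks(read, hit, gi, pi, al)
        return profiler.call_insertion(read, hit, fl, t,
                                       on_target_window=window,
                                       symmetric_window=symmetric)

    def test_rl_event_at_expected_offset_is_on_target(self, scenario):
        call = self._call(scenario, "RL", 49)
        assert (call.orientation, call.offset_bp, call.on_target) == \
            ("RL", 49, True)

    def test_event_beyond_window_is_off_target(self, scenario):
        call = self._call(scenario, "RL", 150)
        assert call.offset_bp == 150 and not call.on_target
        # the symmetric-window option still excludes it
        call2 = self._call(scenario, "RL", 150, symmetric=True)
        assert not call2.on_target

    def test_mirrored_lr_event_has_same_offset(self, scenario):
        call = self._call(scenario, "LR", 49)
        assert (call.orientation, call.offset_bp) == ("LR", 49)

    def test_unplaceable_without_genomic_flank(self, scenario):
        t, v = scenario["target"], scenario["vector"]
        rng = np.random.default_rng(4)
        al = LocalAligner()
        gi = KmerIndex(scenario["genome"].sequence, al.word_size)
        pi = KmerIndex(v.seq, al.word_size)
        unit = scenario["transposon"].seq
        seq = random_dna(rng, 400) + unit + random_dna(rng, 400)
        read = _read(seq)
        hit = profiler.locate_cargo(read, scenario["transposon"], al)
        fl = profiler.classify_flanks(read, hit, gi, pi, al)
        assert profiler.call_insertion(read, hit, fl, t) == "unplaceable"


@pytest.fixture(scope="module")
def run_noisy(scenario, noisy_reads):
    reads, truth_df = noisy_reads
    calls, summary, rej = profiler.profile_reads(
        reads, scenario["genome"].sequence, scenario["vector"].seq,
        scenario["transposon"], scenario["target"])
    return calls, summary, rej, truth_df


class TestPipeline:
    def test_filter_chain_monotone(self, run_noisy):
        _, s, _, _ = run_noisy
        assert s.n_input >= s.n_pass_qc >= s.n_ge_10kb >= s.n_cargo >= s.n_called

    def test_exact_truth_recovery_at_zero_error(self, scenario, clean_reads):
        """Orientation, offset, on-target and cointegrate labels match the
        simulation truth for every placeable error-free read."""
        reads, truth_df = clean_reads
        calls, summary, rej = profiler.profile_reads(
            reads, scenario["genome"].sequence, scenario["vector"].seq,
            scenario["transposon"], scenario["target"])
        m = calls.merge(truth_df, on="read_id", suffixes=("_c", "_t"))
        assert len(m) == len(reads)
        assert (m.orientation_c == m.orientation_t).all()
        assert (m.offset_bp_c == m.offset_bp_t).all()
        assert (m.on_target_c == m.on_target_t).all()
        assert (m.cointegrate_c == m.cointegrate_t).all()
        assert (m.junction == m.position).all()

    def test_noisy_reads_recover_rates_and_modal_offset(self, run_noisy):
        calls, summary, rej, truth_df = run_noisy
        true_pct = 100 * truth_df.on_target.mean()
        assert summary.on_target_pct == pytest.approx(true_pct, abs=2.0)
        modal = max(summary.offset_hist, key=summary.offset_hist.get)
        assert modal == 49
        k = int(round(summary.cointegrate_pct / 100 * summary.n_called))
        lo, hi = binomial_ci(k, summary.n_called)
        assert lo <= truth_df.cointegrate.mean() <= hi

    def test_strand_symmetry_of_summaries(self, scenario, clean_reads):
        """Profiling against the reverse-complemented genome and mirrored
        target yields identical calls."""
        reads, _ = clean_reads
        g, t = scenario["genome"], scenario["target"]
        L = len(g.sequence)
        g_rc = SimGenome(revcomp(g.sequence), [], name="rc")
        t_rc = Target(t.protospacer, t.pam, "-" if t.strand == "+" else "+",
                      L - t.proto_end, L - t.proto_start)
        base, s1, _ = profiler.profile_reads(
            reads, g.sequence, scenario["vector"].seq,
            scenario["transposon"], t)
        mirror, s2, _ = profiler.profile_reads(
            reads, g_rc.sequence, scenario["vector"].seq,
            scenario["transposon"], t_rc)
        m = base.merge(mirror, on="read_id", suffixes=("_f", "_r"))
        assert len(m) == len(base)
        assert (m.orientation_f == m.orientation_r).all()
        assert (m.offset_bp_f == m.offset_bp_r).all()
        assert (m.on_target_f == m.on_target_r).all()
        assert (m.junction_f == L - m.junction_r).all()
        assert s1.on_target_pct == s2.on_target_pct
        assert s1.orientation_fractions == s2.orientation_fractions

    def test_empty_calls_give_empty_sentinel(self):
        s = profiler.summarize([], genome_length=1000)
        assert s.empty and s.n_called == 0
        assert np.isnan(s.on_target_pct)

    def test_summary_json_roundtrip(self, run_noisy, tmp_path):
        import json

        _, summary, _, _ = run_noisy
        path = tmp_path / "summary.json"
        summary.to_json(path)
        data = json.loads(path.read_text())
        assert data["n_called"] == summary.n_called
        assert data["offset_hist"]["49"] == summary.offset_hist[49]
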