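import numpy as np
import pytest

from srnaclass.io_formats import GenomeSeq, Interval, Locus, ReadEntry, ValidationError
from srnaclass.synthetic_data import SimConfig, build_genome_and_loci, simulate_reads
from srnaclass.tailing import (
    ArmIndex,
    asymmetry_test,
    assign_read,
    call_tail,
    call_tails,
    tailing_profile,
    TailingProfile,
)


def _world():
    """Two hand-built plus-strand loci; the second duplicates arm sequence."""
    arm = "GTACGTACGTACGTACGTACCG"  # 22 nt, ends in G (not A)
    arm2 = "ATTGCCGGAACCGGTTAAGGCC"
    filler = "C" * 30
    seq = (
        filler + arm + "G" + "C" * 37  # locus1: arm5p only, downstream base G
        + filler + arm2 + "A" + "C" * 37
        + filler + arm2 + "T" + "C" * 37  # locus3 shares arm2's sequence
    )
    g = GenomeSeq("c", seq)
    mk = lambda lid, start: Locus(lid, "c", "+", Interval(start, start + 60),
                                  arm5p=Interval(start, start + 22))
    l1 = mk("locA", 30)
    l2 = mk("locB", 30 + 60 + 30)
    l3 = mk("locC", 2 * (60 + 30) + 30)
    index = ArmIndex.build([l1, l2, l3], {"c": g})
    return g, (l1, l2, l3), index, arm, arm2


class TestAssignRead:
    def test_exact_read_assigned_weight_one(self):
        _, _, index, arm, _ = _world()
        (asn,) = assign_read(arm, index)
        assert asn.arm_id == "locA_5p" and asn.weight == 1.0 and asn.start_offset == 0

    def test_identical_reference_arms_share_fractional_weight(self):
        _, _, index, _, arm2 = _world()
        asns = assign_read(arm2, index)
        assert sorted(a.arm_id for a in asns) == ["locB_5p", "locC_5p"]
        assert all(a.weight == 0.5 for a in asns)

    def test_anchor_mismatch_unassigned(self):
        _, _, index, arm, _ = _world()
        assert assign_read("T" + arm[1:], index) == []


class TestCallTail:
    def test_untemplated_a_on_one_nt_trimmed_isoform(self):
        _, _, index, arm, _ = _world()
        read = arm[:-1] + "A"  # trimmed by 1 then adenylated; downstream != A
        (asn,) = assign_read(read, index)
        call = call_tail(read, asn, index)
        assert call.tail == "A" and call.tail_class == "A"
        assert call.trim_offset == -1 and call.templated_length == 21

    def test_exact_reference_read(self):
        _, _, index, arm, _ = _world()
        (asn,) = assign_read(arm, index)
        call = call_tail(arm, asn, index)
        assert call.tail == "" and call.tail_class == "none" and call.trim_offset == 0

    def test_templated_extension_not_called_a_tail(self):
        # locA's first downstream genomic base is G: a read ending in that G
        # is templated (trim +1), not an untemplated G tail
        _, _, index, arm, _ = _world()
        read = arm + "G"
        (asn,) = assign_read(read, index)
        call = call_tail(read, asn, index)
        assert call.tail == "" and call.trim_offset == 1

    def test_mixed_tail_called_other(self):
        _, _, index, arm, _ = _world()
        read = arm[:-2] + "AG"
        (asn,) = assign_read(read, index)
        assert call_tail(read, asn, index).tail_class == "other"

    def test_matches_bruteforce_maximal_prefix_oracle(self):
        cfg = SimConfig(seed=5, n_loci_per_class=2, reads_per_arm=60, n_replicates=1)
        genomes, loci, manifest = build_genome_and_loci(cfg)
        entries = simulate_reads(cfg, manifest)
        index = ArmIndex.build(loci, {g.contig_id: g for g in genomes})
        n = 0
        for e in entries:
            for asn in assign_read(e.sequence, index):
                call = call_tail(e.sequence, asn, index)
                ref = index.extended_reference(asn.arm_id, asn.start_offset)
                # oracle: maximal t with read[:t] == ref[:t]
                t_best = max(
                    t for t in range(len(e.sequence) + 1)
                    if e.sequence[:t] == ref[:t]
                )
                assert call.templated_length == t_best
                assert call.tail == e.sequence[t_best:]
                n += e.copy_number
        assert n > 100


class TestTailingProfile:
    def _calls(self, index, arm, n_plain, n_tailed):
        reads = [ReadEntry(arm, n_plain, "s")] if n_plain else []
        if n_tailed:
            reads.append(ReadEntry(arm[:-1] + "A", n_tailed, "s"))
        return call_tails(reads, index)

    def test_percent_arithmetic(self):
        _, _, index, arm, _ = _world()
        prof = tailing_profile(self._calls(index, arm, 90, 10))
        p = prof["locA_5p"]
        assert p.pct["A"] == pytest.approx(10.0)
        assert p.pct["none"] == pytest.approx(90.0)
        assert sum(p.pct.values()) == pytest.approx(100.0)

    def test_low_rpm_arm_excluded(self):
        _, _, index, arm, arm2 = _world()
        calls = call_tails(
            [ReadEntry(arm, 2_000_000, "s"), ReadEntry(arm2, 1, "s")], index
        )
        prof = tailing_profile(calls, min_rpm=1.0)
        assert "locA_5p" in prof and "locB_5p" not in prof

    def test_isoform_table_conserves_weighted_reads(self):
        _, _, index, arm, _ = _world()
        prof = tailing_profile(self._calls(index, arm, 70, 30))
        p = prof["locA_5p"]
        assert sum(p.isoform_table.values()) == pytest.approx(p.total_reads)

    def test_empty_calls_empty_profile(self):
        assert tailing_profile([]) == {}


def _flat_profile(arm_id, pct_a):
    pct = {"none": 100.0 - pct_a, "A": pct_a, "U": 0.0, "C": 0.0, "G": 0.0, "other": 0.0}
    return TailingProfile(arm_id, 1000.0, pct, {}, [], 1000.0)


class TestAsymmetry:
    def test_equal_percentages_give_p_one(self):
        profs = {f"l{i}_3p": _flat_profile(f"l{i}_3p", 5.0) for i in range(3)}
        profs |= {f"l{i}_5p": _flat_profile(f"l{i}_5p", 5.0) for i in range(3)}
        stat = asymmetry_test(profs, "A", n_perm=500, seed=0)
        assert stat.delta == 0.0 and stat.permutation_p == 1.0

    def test_planted_3p_skew_detected(self):
        cfg = SimConfig(
            seed=11, n_loci_per_class=6, classes=("polIII_noncanonical",),
            reads_per_arm=2000, n_replicates=1,
        )
        genomes, loci, manifest = build_genome_and_loci(cfg)
        entries = simulate_reads(cfg, manifest)
        index = ArmIndex.build(loci, {g.contig_id: g for g in genomes})
        prof = tailing_profile(call_tails(entries, index))
        stat = asymmetry_test(prof, "A", n_perm=10000, seed=0)
        assert stat.n_3p == 6 and stat.n_5p == 6
        assert stat.permutation_p < 0.05
        assert stat.delta == pytest.approx(10.0, abs=2.0)

    def test_add_one_lower_bound(self):
        profs = {f"l{i}_3p": _flat_profile(f"l{i}_3p", 50.0) for i in range(2)}
        profs |= {f"l{i}_5p": _flat_profile(f"l{i}_5p", 0.0) for i in range(2)}
        stat = asymmetry_test(profs, "A", n_perm=1000, seed=0)
        assert stat.permutation_p >= 1 / 1001

    def test_too_few_arms_errors(self):
        profs = {"a_3p": _flat_profile("a_3p", 1.0), "b_5p": _flat_profile("b_5p", 1.0)}
        with pytest.raises(ValidationError, match="2 arms"):
            asymmetry_test(profs, "A")
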