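import numpy as np
import pytest

from srnaclass.hairpin import fold_maxpair, hairpin_report, parse_dotbracket
from srnaclass.io_formats import sense_slice
from srnaclass.pol3 import pol3_report
from srnaclass.synthetic_data import (
    CLASSES,
    SimConfig,
    build_genome_and_loci,
    simulate_counts,
    simulate_reads,
)


class TestBuildGenomeAndLoci:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=9, n_loci_per_class=2)
        g1, l1, m1 = build_genome_and_loci(cfg)
        g2, l2, m2 = build_genome_and_loci(SimConfig(seed=9, n_loci_per_class=2))
        assert g1[0].sequence == g2[0].sequence
        assert l1 == l2
        assert m1.to_frame().equals(m2.to_frame())

    def test_different_seed_different_sequence_same_schema(self):
        g1, l1, _ = build_genome_and_loci(SimConfig(seed=1, n_loci_per_class=1))
        g2, l2, _ = build_genome_and_loci(SimConfig(seed=2, n_loci_per_class=1))
        assert g1[0].sequence != g2[0].sequence
        assert [l.locus_id for l in l1] == [l.locus_id for l in l2]

    def test_pol3_locus_planted_geometry(self):
        cfg = SimConfig(seed=42, classes=("polIII_noncanonical",), n_loci_per_class=1)
        genomes, loci, manifest = build_genome_and_loci(cfg)
        t = manifest.loci[0]
        assert -87 <= t.box_a_offset <= -79
        assert -42 <= t.box_b_offset <= -35
        assert -103 <= t.tss_offset <= -101
        assert t.terminator_gap in (3, 4)
        rep = pol3_report(loci[0], genomes[0])
        assert rep.pol3_architecture and rep.boxA_hit.offset == t.box_a_offset

    def test_planted_stem_recovered_by_folding(self):
        cfg = SimConfig(seed=3, classes=("canonical", "mirtron_like"), n_loci_per_class=2)
        genomes, loci, manifest = build_genome_and_loci(cfg)
        for locus, truth in zip(loci, manifest.loci):
            seq = sense_slice(genomes[0], locus, 0, len(locus.precursor))
            n_pairs = len(parse_dotbracket(fold_maxpair(seq)))
            # the fold finds at least the constructed stem, at most a couple
            # of extra loop/bulge pairs
            assert truth.stem_pairs <= n_pairs <= truth.stem_pairs + 4

    def test_mature_species_length_and_first_nt(self):
        cfg = SimConfig(seed=4, classes=("piRNA_like", "siRNA26G_like"), n_loci_per_class=2)
        _, _, manifest = build_genome_and_loci(cfg)
        for t in manifest.loci:
            (arm_seq,) = t.arm_seqs.values()
            if t.cls == "piRNA_like":
                assert len(arm_seq) == 21 and arm_seq[0] == "T"
            else:
                assert len(arm_seq) == 26 and arm_seq[0] == "G"

    def test_every_class_constructible(self):
        _, loci, manifest = build_genome_and_loci(SimConfig(seed=5, n_loci_per_class=1))
        assert {t.cls for t in manifest.loci} == set(CLASSES)
        assert len(loci) == len(CLASSES)


class TestSimulateCounts:
    def test_null_model_condition_means_agree(self):
        lfc0 = {c: {k: 0.0 for k in ("MP_depleted", "Dicer_depleted", "PolIII_depleted")}
                for c in CLASSES}
        cfg = SimConfig(seed=6, classes=("canonical",), n_loci_per_class=2,
                        n_replicates=50, planted_lfc=lfc0, sample_scale_sd=0.0)
        _, _, manifest = build_genome_and_loci(cfg)
        cm = simulate_counts(cfg, manifest)
        by_cond = cm.counts.T.groupby(cm.condition).mean()
        ratios = by_cond / by_cond.loc["control"]
        assert np.allclose(ratios, 1.0, atol=0.15)

    def test_planted_lfc_recovered(self):
        cfg = SimConfig(seed=7, classes=("canonical",), n_loci_per_class=10,
                        n_replicates=20, sample_scale_sd=0.0)
        _, _, manifest = build_genome_and_loci(cfg)
        cm = simulate_counts(cfg, manifest)
        ctrl = cm.counts[cm.samples_for("control")].mean(axis=1)
        dep = cm.counts[cm.samples_for("Dicer_depleted")].mean(axis=1)
        lfc = np.log2(dep / ctrl)
        assert lfc.mean() == pytest.approx(-2.0, abs=0.3)

    def test_zero_dispersion_is_poisson_limit(self):
        cfg = SimConfig(seed=8, classes=("piRNA_like",), n_loci_per_class=1,
                        n_replicates=200, nb_dispersion=0.0, sample_scale_sd=0.0)
        _, _, manifest = build_genome_and_loci(cfg)
        cm = simulate_counts(cfg, manifest)
        ctrl = cm.counts[cm.samples_for("control")].iloc[0]
        assert ctrl.var() / ctrl.mean() == pytest.approx(1.0, rel=0.35)

    def test_spikes_positive_and_condition_independent(self):
        cfg = SimConfig(seed=9, classes=("canonical",), n_loci_per_class=1,
                        n_replicates=30, sample_scale_sd=0.0)
        _, _, manifest = build_genome_and_loci(cfg)
        cm = simulate_counts(cfg, manifest)
        assert (cm.spike_counts > 0).all()
        by_cond = cm.spike_counts.groupby(cm.condition).mean()
        assert np.allclose(by_cond / by_cond.mean(), 1.0, atol=0.05)


class TestSimulateReads:
    def test_no_trim_no_tail_reads_equal_reference(self):
        cfg = SimConfig(seed=10, classes=("canonical",), n_loci_per_class=1,
                        n_replicates=1, trim_model={0: 1.0}, tail_model={},
                        reads_per_arm=50)
        _, _, manifest = build_genome_and_loci(cfg)
        entries = simulate_reads(cfg, manifest)
        refs = set()
        for t in manifest.loci:
            refs |= set(t.arm_seqs.values())
        assert {e.sequence for e in entries} == refs

    def test_tail_fraction_binomial(self):
        cfg = SimConfig(seed=11, classes=("polIII_noncanonical",), n_loci_per_class=1,
                        n_replicates=1, reads_per_arm=10000)
        _, _, manifest = build_genome_and_loci(cfg)
        entries = simulate_reads(cfg, manifest)
        t = manifest.loci[0]
        ref3p = t.arm_seqs["3p"]
        n3p = tailed = 0
        for e in entries:
            if e.sequence.startswith(ref3p[:16]):
                n3p += e.copy_number
                body = e.sequence
                for trim in (0, -1, -2, -3):
                    base = ref3p[: len(ref3p) + trim]
                    if body.startswith(base) and body != base and set(body[len(base):]) == {"A"}:
                        tailed += e.copy_number
                        break
        assert n3p == 10000
        assert tailed / n3p == pytest.approx(0.10, abs=0.01)

    def test_tails_concentrate_on_minus_one_isoform(self):
        cfg = SimConfig(seed=12, classes=("polIII_noncanonical",), n_loci_per_class=2,
                        n_replicates=1, reads_per_arm=3000)
        _, _, manifest = build_genome_and_loci(cfg)
        entries = simulate_reads(cfg, manifest)
        from collections import Counter

        lengths = Counter()
        for t in manifest.loci:
            ref = t.arm_seqs["3p"]
            for e in entries:
                if e.sequence.startswith(ref[:16]) and e.sequence.endswith("A"):
                    # templated body length = longest matching prefix of ref
                    k = 0
                    while k < min(len(e.sequence), len(ref)) and e.sequence[k] == ref[k]:
                        k += 1
                    lengths[k - len(ref)] += e.copy_number
        assert lengths and max(lengths, key=lengths.get) == -1

    def test_read_truth_recorded(self):
        cfg = SimConfig(seed=13, classes=("mirtron_like",), n_loci_per_class=1,
                        n_replicates=2, reads_per_arm=100)
        _, _, manifest = build_genome_and_loci(cfg)
        simulate_reads(cfg, manifest)
        rt = manifest.read_truth
        assert rt is not None and rt["n_reads"].sum() == 2 * 2 * 100
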