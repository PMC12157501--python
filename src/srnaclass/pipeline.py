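"""End-to-end orchestration: file bundle in, evidence + labels out.

Stage order: io -> tailing (if reads are provided) -> differential
abundance per contrast -> hairpin -> Pol III scan -> classification.  All
randomness (the permutation test) flows through the single configured
seed, and output tables carry a provenance header (version, seed, config
hash), so re-running an identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    ClassLabel,
    EvidenceVector,
    Thresholds,
    chip_overlap,
    classify_locus,
)
from .diffabund import diff_table
from .hairpin import HairpinReport, fold_maxpair, hairpin_report
from .io_formats import (
    CountMatrix,
    GenomeSeq,
    Locus,
    read_bed,
    read_collapsed_fasta,
    read_counts_tsv,
    read_dotbracket,
    read_fasta,
    read_loci_gff3,
    sense_slice,
    write_bed,
    write_collapsed_fasta,
    write_counts_tsv,
    write_dotbracket,
    write_fasta,
    write_loci_gff3,
)
from .pol3 import PolIIIReport, ScanConfig, pol3_report
from .tailing import (
    ArmIndex,
    AsymmetryStat,
    TailingProfile,
    asymmetry_test,
    average_profiles,
    call_tails,
    tailing_profile,
)

__all__ = ["RunConfig", "RunResult", "run_all", "make_demo", "demo_config"]


@dataclass
class RunConfig:
    genome: str
    loci: str
    counts: str
    contrasts: list  # (name, treat_condition, ctrl_condition); MP*/Dicer*/PolIII* roles
    reads: dict = field(default_factory=dict)  # sample_id -> collapsed FASTA path
    peaks: str | None = None
    structures: str | None = None
    outdir: str = "srnaclass_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    spike_prefix: str = "spike_"
    hairpin_threshold: int = 32
    min_rpm: float = 1.0
    base_mean_filter: float = 10.0
    pseudocount: float = 0.5
    a_tail_bias_pp: float = 5.0  # 3p-vs-5p %A gap calling a locus A-tail-biased
    n_perm: int = 10000

    def validate(self) -> None:
        if not self.contrasts:
            raise ValueError("at least one contrast is required")
        for p in [self.genome, self.loci, self.counts, self.peaks, self.structures,
                  *self.reads.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(asdict(self).items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    labels: dict[str, ClassLabel]
    evidence: dict[str, EvidenceVector]
    diff: dict[str, pd.DataFrame]
    hairpin: dict[str, HairpinReport]
    pol3: dict[str, PolIIIReport]
    profiles: dict[str, TailingProfile]
    asymmetry: AsymmetryStat | None
    outputs: dict[str, str]


def _contrast_role(name: str) -> str:
    u = name.upper()
    if u.startswith("MP"):
        return "MP"
    if "DICER" in u:
        return "Dicer"
    if "POL" in u:
        return "PolIII"
    return "other"


def _representative_arm(df: pd.DataFrame, locus: Locus) -> str | None:
    arm_ids = [locus.arm_id(w) for w in ("5p", "3p") if locus.arm(w) is not None]
    present = [a for a in arm_ids if a in df.index]
    if not present:
        return None
    return max(present, key=lambda a: df.loc[a, "baseMean"])


def _provenance(cfg: RunConfig) -> str:
    return f"# srnaclass {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t")


def run_all(cfg: RunConfig) -> RunResult:
    """Run every stage on a file bundle and write the result tables."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # --- io
    genomes = {g.contig_id: g for g in read_fasta(cfg.genome)}
    loci = read_loci_gff3(cfg.loci)
    cm = read_counts_tsv(cfg.counts, spike_prefix=cfg.spike_prefix)
    peaks = read_bed(cfg.peaks) if cfg.peaks else []
    structures = read_dotbracket(cfg.structures) if cfg.structures else {}

    # --- tailing (optional stage)
    profiles: dict[str, TailingProfile] = {}
    asym: AsymmetryStat | None = None
    locus_len_counts: dict[str, Counter] = defaultdict(Counter)
    locus_nt_counts: dict[str, Counter] = defaultdict(Counter)
    if cfg.reads:
        index = ArmIndex.build(loci, genomes)
        per_sample_profiles = []
        for sample_id, path in sorted(cfg.reads.items()):
            entries = read_collapsed_fasta(path, sample_id)
            calls = call_tails(entries, index)
            per_sample_profiles.append(tailing_profile(calls, min_rpm=cfg.min_rpm))
            for c in calls:
                locus_id = c.arm_id.rsplit("_", 1)[0]
                locus_len_counts[locus_id][len(c.read_sequence)] += c.weight
                locus_nt_counts[locus_id][c.read_sequence[0].replace("T", "U")] += c.weight
        profiles = average_profiles(per_sample_profiles)
        try:
            asym = asymmetry_test(profiles, "A", n_perm=cfg.n_perm, seed=cfg.seed)
        except ValueError:
            asym = None

    # --- differential abundance per contrast
    diff: dict[str, pd.DataFrame] = {}
    for name, treat, ctrl in cfg.contrasts:
        diff[name] = diff_table(
            cm, (treat, ctrl),
            pseudocount=cfg.pseudocount, base_mean_filter=cfg.base_mean_filter,
        )

    # --- hairpin + pol3 per locus
    hairpins: dict[str, HairpinReport] = {}
    pol3s: dict[str, PolIIIReport] = {}
    folded: dict[str, tuple[str, str]] = {}
    for locus in loci:
        if locus.locus_id in structures:
            _, struct = structures[locus.locus_id]
        else:
            seq = sense_slice(genomes[locus.contig_id], locus, 0, len(locus.precursor))
            struct = fold_maxpair(seq)
            folded[locus.locus_id] = (seq, struct)
        hairpins[locus.locus_id] = hairpin_report(
            locus, struct, threshold=cfg.hairpin_threshold
        )
        pol3s[locus.locus_id] = pol3_report(locus, genomes[locus.contig_id], cfg.scan)

    chip = chip_overlap(loci, peaks) if peaks else {l.locus_id: False for l in loci}

    # --- evidence assembly + classification
    mp_names = [n for n, _, _ in cfg.contrasts if _contrast_role(n) == "MP"][:2]
    dicer_name = next((n for n, _, _ in cfg.contrasts if _contrast_role(n) == "Dicer"), None)
    pol3_name = next((n for n, _, _ in cfg.contrasts if _contrast_role(n) == "PolIII"), None)

    evidence: dict[str, EvidenceVector] = {}
    labels: dict[str, ClassLabel] = {}
    for locus in loci:
        lid = locus.locus_id

        def arm_stats(name):
            if name is None:
                return None, None
            df = diff[name]
            arm = _representative_arm(df, locus)
            if arm is None:
                return None, None
            return float(df.loc[arm, "lfc"]), float(df.loc[arm, "p_adj"])

        mp1 = arm_stats(mp_names[0])[0] if len(mp_names) >= 1 else None
        mp2 = arm_stats(mp_names[1])[0] if len(mp_names) >= 2 else None
        lfc_d, p_d = arm_stats(dicer_name)
        lfc_p3, p_p3 = arm_stats(pol3_name)

        dom_len = first_nt = None
        if locus_len_counts.get(lid):
            dom_len = int(max(locus_len_counts[lid].items(), key=lambda kv: kv[1])[0])
            first_nt = max(locus_nt_counts[lid].items(), key=lambda kv: kv[1])[0]

        pct_a_3p = pct_a_5p = None
        p3 = profiles.get(locus.arm_id("3p"))
        p5 = profiles.get(locus.arm_id("5p"))
        if p3 is not None:
            pct_a_3p = p3.pct_tailed("A")
        if p5 is not None:
            pct_a_5p = p5.pct_tailed("A")
        a_bias = (
            pct_a_3p is not None
            and pct_a_5p is not None
            and pct_a_3p - pct_a_5p > cfg.a_tail_bias_pp
        )

        ev = EvidenceVector(
            locus_id=lid,
            lfc_MP_1=mp1,
            lfc_MP_2=mp2,
            lfc_dicer=lfc_d,
            p_adj_dicer=p_d,
            lfc_polIII=lfc_p3,
            p_adj_polIII=p_p3,
            short_hairpin=hairpins[lid].short_hairpin,
            polIII_architecture=pol3s[lid].pol3_architecture,
            chip_overlap=chip.get(lid, False),
            dominant_length=dom_len,
            first_nt=first_nt,
            a_tail_3p_bias=a_bias,
        )
        evidence[lid] = ev
        labels[lid] = classify_locus(ev, cfg.thresholds)

    # --- outputs
    for name, df in diff.items():
        path = outdir / f"diff_{name}.tsv"
        _write_tsv(path, df, cfg)
        outputs[f"diff_{name}"] = str(path)

    hp_df = pd.DataFrame(
        [
            {
                "locus_id": h.locus_id,
                "stem_pairs": h.stem_pairs,
                "short_hairpin": h.short_hairpin,
                "unpaired_5p_flank": h.unpaired_5p_flank,
                "unpaired_3p_flank": h.unpaired_3p_flank,
            }
            for h in hairpins.values()
        ]
    ).set_index("locus_id")
    _write_tsv(outdir / "hairpin.tsv", hp_df, cfg)
    outputs["hairpin"] = str(outdir / "hairpin.tsv")

    p3_df = pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "boxA_offset": r.boxA_hit.offset if r.boxA_hit else "",
                "boxA_mismatches": r.boxA_hit.mismatches if r.boxA_hit else "",
                "boxB_offset": r.boxB_hit.offset if r.boxB_hit else "",
                "boxB_mismatches": r.boxB_hit.mismatches if r.boxB_hit else "",
                "proximal_term_offset": r.proximal_terminator.offset if r.proximal_terminator else "",
                "proximal_term_len": r.proximal_terminator.length if r.proximal_terminator else "",
                "distal_term_offset": r.distal_terminator.offset if r.distal_terminator else "",
                "tss_estimate_heuristic": r.tss_estimate if r.tss_estimate is not None else "",
                "pol3_architecture": r.pol3_architecture,
            }
            for r in pol3s.values()
        ]
    ).set_index("locus_id")
    _write_tsv(outdir / "pol3_scan.tsv", p3_df, cfg)
    outputs["pol3_scan"] = str(outdir / "pol3_scan.tsv")

    if profiles:
        prof_df = pd.DataFrame(
            [
                {
                    "arm_id": p.arm_id,
                    "total": round(p.total_reads, 3),
                    "pct_A": round(p.pct.get("A", 0.0), 4),
                    "pct_U": round(p.pct.get("U", 0.0), 4),
                    "pct_C": round(p.pct.get("C", 0.0), 4),
                    "pct_G": round(p.pct.get("G", 0.0), 4),
                    "pct_other": round(p.pct.get("other", 0.0), 4),
                    "RPM": round(p.rpm, 3),
                }
                for p in profiles.values()
            ]
        ).set_index("arm_id")
        _write_tsv(outdir / "tailing_profiles.tsv", prof_df, cfg)
        outputs["tailing_profiles"] = str(outdir / "tailing_profiles.tsv")
        iso_rows = [
            {"arm_id": p.arm_id, "rank": i + 1, "trim_offset": t, "tail_class": cls,
             "count": round(n, 3)}
            for p in profiles.values()
            for i, (t, cls, n) in enumerate(p.top_isoforms)
        ]
        _write_tsv(outdir / "isoforms.tsv", pd.DataFrame(iso_rows).set_index("arm_id"), cfg)
        outputs["isoforms"] = str(outdir / "isoforms.tsv")

    ev_df = pd.DataFrame([asdict(e) for e in evidence.values()]).set_index("locus_id")
    _write_tsv(outdir / "evidence.tsv", ev_df, cfg)
    outputs["evidence"] = str(outdir / "evidence.tsv")

    lab_df = pd.DataFrame(
        [
            {"locus_id": l.locus_id, "label": l.label, "rationale": " | ".join(l.rationale)}
            for l in labels.values()
        ]
    ).set_index("locus_id")
    _write_tsv(outdir / "labels.tsv", lab_df, cfg)
    outputs["labels"] = str(outdir / "labels.tsv")

    if asym is not None:
        with open(outdir / "asymmetry.json", "w") as fh:
            json.dump(
                {
                    "nucleotide": asym.nucleotide,
                    "delta_pct": asym.delta,
                    "permutation_p": asym.permutation_p,
                    "n_3p": asym.n_3p,
                    "n_5p": asym.n_5p,
                    "provenance": _provenance(cfg).strip("# \n"),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        outputs["asymmetry"] = str(outdir / "asymmetry.json")

    if folded:
        write_dotbracket(outdir / "structures.fold", folded)
        outputs["structures"] = str(outdir / "structures.fold")

    return RunResult(
        labels=labels,
        evidence=evidence,
        diff=diff,
        hairpin=hairpins,
        pol3=pol3s,
        profiles=profiles,
        asymmetry=asym,
        outputs=outputs,
    )


def make_demo(seed: int = 42, outdir: str = "demo", config=None):
    """Write the default synthetic bundle plus truth manifest to ``outdir``.

    Returns (paths dict, truth manifest).  Deterministic under the seed.
    """
    from .synthetic_data import (
        SimConfig,
        _POL3_CLASSES,
        build_genome_and_loci,
        simulate_counts,
        simulate_reads,
    )

    cfg = config or SimConfig(seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, loci, manifest = build_genome_and_loci(cfg)
    cm = simulate_counts(cfg, manifest)
    reads = simulate_reads(cfg, manifest)

    paths = {"genome": str(out / "genome.fa"), "loci": str(out / "loci.gff3"),
             "counts": str(out / "counts.tsv"), "peaks": str(out / "peaks.bed"),
             "truth": str(out / "truth.tsv")}
    write_fasta(paths["genome"], genomes)
    write_loci_gff3(paths["loci"], loci)
    write_counts_tsv(paths["counts"], cm)

    read_paths = {}
    by_sample: dict[str, list] = defaultdict(list)
    for e in reads:
        by_sample[e.sample_id].append(e)
    for sid, entries in sorted(by_sample.items()):
        p = out / f"reads_{sid}.fa"
        write_collapsed_fasta(p, entries)
        read_paths[sid] = str(p)

    # emulated Pol III ChIP occupancy over the planted Pol III loci
    peak_rows = []
    pol3_ids = {t.locus_id for t in manifest.loci if t.cls in _POL3_CLASSES}
    for locus in loci:
        if locus.locus_id in pol3_ids:
            peak_rows.append(
                (locus.contig_id, max(0, locus.precursor.start - 50),
                 locus.precursor.end + 50, f"chip_{locus.locus_id}", 0, locus.strand)
            )
    write_bed(paths["peaks"], peak_rows)

    manifest.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["reads"] = read_paths
    return paths, manifest


def demo_config(paths: dict, outdir: str, seed: int = 42) -> RunConfig:
    """RunConfig wired to a bundle written by :func:`make_demo`."""
    return RunConfig(
        genome=paths["genome"],
        loci=paths["loci"],
        counts=paths["counts"],
        reads=dict(paths["reads"]),
        peaks=paths["peaks"],
        contrasts=[
            ("MP_1", "MP_depleted", "control"),
            ("Dicer", "Dicer_depleted", "control"),
            ("PolIII", "PolIII_depleted", "control"),
        ],
        outdir=outdir,
        seed=seed,
    )
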