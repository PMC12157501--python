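"""Synthetic small-RNA-seq study generator with known ground truth.

Emits a toy genome carrying planted loci of every target class, together
with multi-condition count matrices (negative-binomial noise, spike-ins,
planted log2 fold changes) and collapsed read sets with controlled 3'
trimming isoforms and untemplated tails.  Every downstream stage of the
pipeline is testable against the truth manifest with no external data.

Class encodings (defaults; all config-exposed):

* ``canonical`` — 35-pair hairpin, depleted ~4-fold under Microprocessor
  and Dicer loss, unaffected by Pol III loss.
* ``mirtron_like`` — short (25-pair) hairpin, Microprocessor-insensitive
  (slightly up), Dicer-dependent; low-rate 3' uridylation on the 3p arm.
* ``polIII_noncanonical`` — short hairpin plus a full type-II Pol III
  promoter architecture (Box A 79-87 nt and Box B 35-42 nt upstream, TSS
  mark 101-103 nt upstream, a 5T terminator 3-4 nt downstream of the 3p
  arm and a 4-5T run further downstream); Dicer- and Pol III-dependent,
  Microprocessor-insensitive; A-tails planted on the 3p arm concentrated
  on the 1-nt-trimmed isoform.
* ``mp_dicer_independent`` — Pol III architecture and dependence, but
  insensitive to both Microprocessor and Dicer loss.
* ``piRNA_like`` — 21-nt mature species with 5' U (annotated as the 5p
  arm of a 42-nt precursor), no depletion response.
* ``siRNA26G_like`` — 26-nt mature species with 5' G, Dicer-dependent.

The three terminal precursor bases and the first downstream base are drawn
from {C, G} so that planted A/U tails can never be mimicked by the genomic
template at the trim offsets in use; without this, sequence-based tail
calling is structurally blind to ~1/4 of planted tails and the manifest's
planted rates would not be recoverable by any caller.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GenomeSeq,
    Interval,
    Locus,
    ReadEntry,
    revcomp,
)
from .pol3 import ScanConfig, pol3_report

__all__ = [
    "CLASSES",
    "EXPECTED_LABEL",
    "SimConfig",
    "LocusTruth",
    "TruthManifest",
    "build_genome_and_loci",
    "simulate_counts",
    "simulate_reads",
]

CLASSES = (
    "canonical",
    "mirtron_like",
    "polIII_noncanonical",
    "mp_dicer_independent",
    "piRNA_like",
    "siRNA26G_like",
)

EXPECTED_LABEL = {
    "canonical": "canonical",
    "mirtron_like": "mirtron_like",
    "polIII_noncanonical": "polIII_noncanonical",
    "mp_dicer_independent": "mp_dicer_independent",
    "piRNA_like": "misannotated_piRNA",
    "siRNA26G_like": "misannotated_26G",
}

_POL3_CLASSES = {"polIII_noncanonical", "mp_dicer_independent"}
_HAIRPIN_STEMS = {
    "canonical": 35,
    "mirtron_like": 25,
    "polIII_noncanonical": 25,
    "mp_dicer_independent": 25,
}

_DEFAULT_LFC = {
    "canonical": {"MP_depleted": -2.0, "Dicer_depleted": -2.0, "PolIII_depleted": 0.0},
    "mirtron_like": {"MP_depleted": 0.3, "Dicer_depleted": -2.0, "PolIII_depleted": 0.0},
    "polIII_noncanonical": {"MP_depleted": 0.3, "Dicer_depleted": -2.0, "PolIII_depleted": -2.0},
    "mp_dicer_independent": {"MP_depleted": 0.3, "Dicer_depleted": 0.0, "PolIII_depleted": -2.0},
    "piRNA_like": {"MP_depleted": 0.0, "Dicer_depleted": 0.0, "PolIII_depleted": 0.0},
    "siRNA26G_like": {"MP_depleted": 0.0, "Dicer_depleted": -2.0, "PolIII_depleted": 0.0},
}

_DEFAULT_TAILS = {
    "polIII_noncanonical": {"3p": {"A": 0.10}, "5p": {}},
    "mirtron_like": {"3p": {"U": 0.05}, "5p": {}},
}

_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 42
    n_loci_per_class: int = 10
    classes: tuple[str, ...] = CLASSES
    depth_mean: float = 2000.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    conditions: tuple[str, ...] = (
        "control", "MP_depleted", "Dicer_depleted", "PolIII_depleted",
    )
    planted_lfc: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LFC.items()})
    tail_model: dict = field(default_factory=lambda: {k: {a: dict(r) for a, r in v.items()} for k, v in _DEFAULT_TAILS.items()})
    trim_model: dict = field(default_factory=lambda: {0: 0.70, -1: 0.20, -2: 0.07, -3: 0.03})
    tail_trim_model: dict = field(default_factory=lambda: {-1: 0.80, 0: 0.10, -2: 0.10})
    tail_len_probs: tuple[float, ...] = (0.80, 0.15, 0.05)  # tail lengths 1..3
    spike_mean: float = 5000.0
    n_spike_features: int = 3
    sample_scale_sd: float = 0.15
    reads_per_arm: int = 300
    arm_len: int = 22
    loop_len: int = 8
    arm3p_scalar: float = 0.6
    upstream_len: int = 120
    downstream_len: int = 80
    spacer_len: int = 100
    contig_id: str = "chrSim"

    def __post_init__(self):
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        if self.n_loci_per_class < 1 or self.depth_mean <= 0 or self.spike_mean <= 0:
            raise ValueError("n_loci_per_class, depth_mean, spike_mean must be positive")
        if self.nb_dispersion < 0 or self.n_replicates < 1:
            raise ValueError("nb_dispersion must be >= 0, n_replicates >= 1")
        for model in (self.trim_model, self.tail_trim_model):
            if abs(sum(model.values()) - 1.0) > 1e-9 or any(p < 0 for p in model.values()):
                raise ValueError("trim model probabilities must be in [0,1] and sum to 1")
        for cls_rates in self.tail_model.values():
            for arm_rates in cls_rates.values():
                if any(not (0 <= r <= 1) for r in arm_rates.values()):
                    raise ValueError("tail rates must lie in [0,1]")
                if sum(arm_rates.values()) > 1.0 + 1e-9:
                    raise ValueError("tail rates for one arm must sum to <= 1")

    def tail_rates(self, cls: str, arm: str) -> dict[str, float]:
        return self.tail_model.get(cls, {}).get(arm, {})

    def lfc(self, cls: str, condition: str) -> float:
        if condition == "control":
            return 0.0
        return self.planted_lfc.get(cls, {}).get(condition, 0.0)


@dataclass
class LocusTruth:
    locus_id: str
    cls: str
    expected_label: str
    strand: str
    stem_pairs: int | None
    arm_seqs: dict  # arm suffix -> sense sequence
    box_a_offset: int | None
    box_b_offset: int | None
    tss_offset: int | None
    terminator_gap: int | None
    intron_span: tuple[int, int]
    host_gene_id: str


@dataclass
class TruthManifest:
    loci: list[LocusTruth]
    config: SimConfig
    read_truth: pd.DataFrame | None = None

    def truth_for(self, locus_id: str) -> LocusTruth:
        return next(t for t in self.loci if t.locus_id == locus_id)

    def expected_labels(self) -> dict[str, str]:
        return {t.locus_id: t.expected_label for t in self.loci}

    def arm_ids(self) -> list[str]:
        return [f"{t.locus_id}_{arm}" for t in self.loci for arm in sorted(t.arm_seqs)]

    def expected_mean(self, arm_id: str, condition: str) -> float:
        locus_id, arm = arm_id.rsplit("_", 1)
        t = self.truth_for(locus_id)
        scalar = 1.0 if arm == "5p" else self.config.arm3p_scalar
        return self.config.depth_mean * scalar * 2.0 ** self.config.lfc(t.cls, condition)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.loci:
            rows.append(
                {
                    "locus_id": t.locus_id,
                    "class": t.cls,
                    "expected_label": t.expected_label,
                    "strand": t.strand,
                    "stem_pairs": t.stem_pairs if t.stem_pairs is not None else "",
                    "box_a_offset": t.box_a_offset if t.box_a_offset is not None else "",
                    "box_b_offset": t.box_b_offset if t.box_b_offset is not None else "",
                    "tss_offset": t.tss_offset if t.tss_offset is not None else "",
                    "terminator_gap": t.terminator_gap if t.terminator_gap is not None else "",
                    "host_gene_id": t.host_gene_id,
                }
            )
        return pd.DataFrame(rows)


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


def _realize_iupac(rng: np.random.Generator, iupac: str) -> str:
    from .pol3 import IUPAC

    return "".join(rng.choice(list(IUPAC[c])) for c in iupac.upper())


def _build_precursor(rng: np.random.Generator, cls: str, cfg: SimConfig):
    """Return (precursor_seq, arm_spans, stem_pairs) in transcript orientation."""
    if cls in _HAIRPIN_STEMS:
        n_pairs = _HAIRPIN_STEMS[cls]
        # first three stem bases strong (G/C) => precursor ends in S bases,
        # keeping planted tails distinguishable from the template
        stem = _rand_seq(rng, 3, "GC") + _rand_seq(rng, n_pairs - 3)
        loop = _rand_seq(rng, cfg.loop_len)
        prec = stem + loop + revcomp(stem)
        arms = {"5p": (0, cfg.arm_len), "3p": (len(prec) - cfg.arm_len, len(prec))}
        return prec, arms, n_pairs
    if cls == "piRNA_like":
        mature = "T" + _rand_seq(rng, 20)
        prec = mature + _rand_seq(rng, 18) + _rand_seq(rng, 3, "GC")
        return prec, {"5p": (0, 21)}, None
    if cls == "siRNA26G_like":
        mature = "G" + _rand_seq(rng, 25)
        prec = mature + _rand_seq(rng, 23) + _rand_seq(rng, 3, "GC")
        return prec, {"5p": (0, 26)}, None
    raise ValueError(f"unknown class {cls!r}")


def _build_flanks(rng: np.random.Generator, cls: str, cfg: SimConfig, arm3p_gap: int):
    """Random upstream/downstream flanks; pol3 classes get planted elements.

    ``arm3p_gap`` is the distance from the 3p-arm (or precursor) 3' end to
    the precursor 3' end in transcript orientation (0 for hairpin classes).
    Returns (upstream, downstream, plant) where plant records offsets.
    """
    scan = ScanConfig()
    U, D = cfg.upstream_len, cfg.downstream_len
    plant = {"box_a": None, "box_b": None, "tss": None, "term_gap": None}
    if cls not in _POL3_CLASSES:
        upstream = _rand_seq(rng, U)
        downstream = _rand_seq(rng, 1, "GC") + _rand_seq(rng, D - 1)
        return upstream, downstream, plant

    d_a = int(rng.integers(79, 88))    # Box A start 79-87 nt upstream
    d_b = int(rng.integers(35, 43))    # Box B start 35-42 nt upstream
    tss = int(rng.integers(101, 104))  # TSS mark 101-103 nt upstream
    box_a = _realize_iupac(rng, scan.box_a.iupac)
    box_b = _realize_iupac(rng, scan.box_b.iupac)
    gap = int(rng.integers(3, 5))      # 5T run 3-4 nt downstream of 3p-arm end
    gap2 = int(rng.integers(5, 16))    # spacing before the distal 4-5T run
    distal_len = int(rng.integers(4, 6))
    plant.update(box_a=-d_a, box_b=-d_b, tss=-tss, term_gap=gap)

    upstream = list(_rand_seq(rng, U))
    upstream[U - d_a : U - d_a + len(box_a)] = box_a
    upstream[U - d_b : U - d_b + len(box_b)] = box_b
    upstream = "".join(upstream)

    # downstream is laid out relative to the 3p-arm 3' end
    spacer = _rand_seq(rng, 1, "GC") + _rand_seq(rng, gap - 1, "ACG")
    mid = _rand_seq(rng, gap2, "ACG")
    tail_fill = "A" + _rand_seq(rng, D)
    downstream = (spacer + "TTTTT" + mid + "T" * distal_len + tail_fill)
    downstream = downstream[arm3p_gap:][:D]
    return upstream, downstream, plant


def _verify_pol3_plant(cassette: str, prec_span: tuple[int, int], arms: dict,
                       plant: dict, plen_bounds=(40, 200)) -> bool:
    """Check the planted elements are what the scanner reports (best hits)."""
    genome = GenomeSeq("tmp", cassette)
    locus = Locus(
        "tmp", "tmp", "+", Interval(*prec_span),
        arm5p=Interval(prec_span[0] + arms["5p"][0], prec_span[0] + arms["5p"][1]),
        arm3p=Interval(prec_span[0] + arms["3p"][0], prec_span[0] + arms["3p"][1]),
        min_precursor_len=plen_bounds[0], max_precursor_len=plen_bounds[1],
    )
    rep = pol3_report(locus, genome)
    return (
        rep.boxA_hit is not None
        and rep.boxA_hit.offset == plant["box_a"]
        and rep.boxA_hit.mismatches == 0
        and rep.boxB_hit is not None
        and rep.boxB_hit.offset == plant["box_b"]
        and rep.boxB_hit.mismatches == 0
        and rep.proximal_terminator is not None
        and rep.proximal_terminator.offset == plant["term_gap"]
        and rep.proximal_terminator.length == 5
        and rep.distal_terminator is not None
    )


def build_genome_and_loci(config: SimConfig):
    """Construct the toy genome, annotated loci, and truth manifest.

    Deterministic under ``config.seed``: the same seed yields byte-identical
    genome, loci, and manifest.  Loci alternate strands to exercise
    minus-strand extraction end to end.
    """
    rng = np.random.default_rng([config.seed, 0])
    pieces: list[str] = []
    offset = 0
    loci: list[Locus] = []
    truths: list[LocusTruth] = []
    i = 0
    for cls in config.classes:
        for _ in range(config.n_loci_per_class):
            prec, arms, stem_pairs = _build_precursor(rng, cls, config)
            plen = len(prec)
            for attempt in range(100):
                up, down, plant = _build_flanks(rng, cls, config, arm3p_gap=0)
                cassette = up + prec + down
                span = (config.upstream_len, config.upstream_len + plen)
                if cls not in _POL3_CLASSES or _verify_pol3_plant(cassette, span, arms, plant):
                    break
            else:  # pragma: no cover - resampling virtually always succeeds
                raise RuntimeError(f"could not plant pol3 elements for {cls} locus")

            strand = "+" if i % 2 == 0 else "-"
            locus_id = f"L{i:03d}_{cls}"
            spacer = _rand_seq(rng, config.spacer_len)
            pieces.append(spacer)
            g0 = offset + len(spacer)
            L = len(cassette)
            if strand == "+":
                pieces.append(cassette)
                prec_ivl = Interval(g0 + config.upstream_len, g0 + config.upstream_len + plen)
            else:
                pieces.append(revcomp(cassette))
                prec_ivl = Interval(g0 + config.downstream_len, g0 + config.downstream_len + plen)
            offset = g0 + L

            def to_genomic(rel):
                a, b = rel
                if strand == "+":
                    return Interval(prec_ivl.start + a, prec_ivl.start + b)
                return Interval(prec_ivl.end - b, prec_ivl.end - a)

            host = f"host_{i % 3}"
            loci.append(
                Locus(
                    locus_id=locus_id,
                    contig_id=config.contig_id,
                    strand=strand,
                    precursor=prec_ivl,
                    arm5p=to_genomic(arms["5p"]) if "5p" in arms else None,
                    arm3p=to_genomic(arms["3p"]) if "3p" in arms else None,
                    host_gene_id=host,
                )
            )
            truths.append(
                LocusTruth(
                    locus_id=locus_id,
                    cls=cls,
                    expected_label=EXPECTED_LABEL[cls],
                    strand=strand,
                    stem_pairs=stem_pairs,
                    arm_seqs={a: prec[s:e] for a, (s, e) in arms.items()},
                    box_a_offset=plant["box_a"],
                    box_b_offset=plant["box_b"],
                    tss_offset=plant["tss"],
                    terminator_gap=plant["term_gap"],
                    intron_span=(g0, g0 + L),
                    host_gene_id=host,
                )
            )
            i += 1
    pieces.append(_rand_seq(rng, config.spacer_len))
    genome = GenomeSeq(config.contig_id, "".join(pieces))
    return [genome], loci, TruthManifest(loci=truths, config=config)


def _sample_ids(config: SimConfig) -> list[tuple[str, str]]:
    return [
        (f"{cond}_{r}", cond)
        for cond in config.conditions
        for r in range(1, config.n_replicates + 1)
    ]


def simulate_counts(config: SimConfig, manifest: TruthManifest) -> CountMatrix:
    """Draw the arm x sample count matrix with spike-ins.

    Counts are NB(mean = depth * 2^planted_lfc * arm_scalar * sample_scale,
    Var = mu + alpha mu^2); spike features are Poisson and independent of
    condition apart from the shared per-sample technical scale.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = _sample_ids(config)
    scales = np.exp(rng.normal(0.0, config.sample_scale_sd, size=len(samples)))

    arm_ids = manifest.arm_ids()
    data = np.zeros((len(arm_ids), len(samples)), dtype=np.int64)
    for fi, arm_id in enumerate(arm_ids):
        for sj, (sid, cond) in enumerate(samples):
            mu = manifest.expected_mean(arm_id, cond) * scales[sj]
            if config.nb_dispersion > 0:
                n = 1.0 / config.nb_dispersion
                data[fi, sj] = rng.negative_binomial(n, n / (n + mu))
            else:
                data[fi, sj] = rng.poisson(mu)

    spike = np.zeros(len(samples), dtype=np.int64)
    per_spike = config.spike_mean / config.n_spike_features
    for sj in range(len(samples)):
        spike[sj] = max(
            1, int(rng.poisson(per_spike * scales[sj], size=config.n_spike_features).sum())
        )

    sample_ids = [s for s, _ in samples]
    counts = pd.DataFrame(data, index=arm_ids, columns=sample_ids)
    return CountMatrix(
        counts=counts,
        spike_counts=pd.Series(spike, index=sample_ids),
        condition=pd.Series([c for _, c in samples], index=sample_ids),
    )


def simulate_reads(config: SimConfig, manifest: TruthManifest) -> list[ReadEntry]:
    """Emit collapsed reads for the control replicates.

    Each read is the arm reference trimmed at the 3' end by an offset drawn
    from the trim model, then with the class/arm-specific probability a
    mononucleotide tail of length 1-3 is appended.  Tailed reads draw their
    trim offset from a distribution concentrated on the -1 isoform, so
    tailing marks a 1-nt-shortened precursor intermediate.  The per-read
    truth is aggregated into ``manifest.read_truth``.
    """
    rng = np.random.default_rng([config.seed, 2])
    trim_keys = np.array(sorted(config.trim_model, reverse=True))
    trim_p = np.array([config.trim_model[k] for k in trim_keys])
    ttrim_keys = np.array(sorted(config.tail_trim_model, reverse=True))
    ttrim_p = np.array([config.tail_trim_model[k] for k in ttrim_keys])
    tlen_p = np.array(config.tail_len_probs)
    tlen_vals = np.arange(1, len(tlen_p) + 1)

    entries: list[ReadEntry] = []
    truth_rows = []
    control_samples = [f"control_{r}" for r in range(1, config.n_replicates + 1)]
    for t in manifest.loci:
        for arm in sorted(t.arm_seqs):
            ref = t.arm_seqs[arm]
            rates = config.tail_rates(t.cls, arm)
            nts = list(rates)
            cum = np.cumsum([rates[nt] for nt in nts]) if nts else np.array([])
            for sid in control_samples:
                n = config.reads_per_arm
                u = rng.random(n)
                tail_idx = np.searchsorted(cum, u) if nts else np.full(n, 0)
                tailed = (u < cum[-1]) if nts else np.zeros(n, dtype=bool)
                trims = np.where(
                    tailed,
                    rng.choice(ttrim_keys, size=n, p=ttrim_p),
                    rng.choice(trim_keys, size=n, p=trim_p),
                )
                tlens = rng.choice(tlen_vals, size=n, p=tlen_p)
                counter: Counter[str] = Counter()
                for k in range(n):
                    body = ref[: len(ref) + int(trims[k])]
                    if tailed[k]:
                        nt = nts[int(tail_idx[k])].replace("U", "T")
                        counter[body + nt * int(tlens[k])] += 1
                    else:
                        counter[body] += 1
                for seq, c in sorted(counter.items()):
                    entries.append(ReadEntry(seq, c, sid))
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "arm_id": f"{t.locus_id}_{arm}",
                        "n_reads": n,
                        "n_tailed": int(tailed.sum()),
                        "planted_tail_rate": float(sum(rates.values())),
                    }
                )
    manifest.read_truth = pd.DataFrame(truth_rows)
    return entries
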