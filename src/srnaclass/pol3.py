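"""RNA polymerase III type-II promoter architecture scanning.

Type-II Pol III genes (tRNA-like) carry internal/proximal Box A and Box B
promoter elements downstream of the TSS and terminate at runs of >= 4-5 T
on the sense strand.  For noncanonical small-RNA loci of this type the
expected geometry, transcript-relative to the precursor start, is: Box A
starting 79-87 nt upstream, Box B 35-42 nt upstream, a 5T terminator
beginning 3-4 nt downstream of the 3p-arm 3' end, and often a second 4-5T
run within a few tens of nucleotides further downstream.

The consensus motifs are configuration, not constants: the default Box A
``TRGCNNARYNNG`` and Box B ``GWTCRANNC`` are the standard eukaryotic
tRNA-derived consensi and should be replaced when an organism-specific
consensus is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import GenomeSeq, Locus, sense_slice, arm_transcript_span

__all__ = [
    "MotifDef",
    "MotifHit",
    "TRun",
    "ScanConfig",
    "PolIIIReport",
    "scan_iupac",
    "find_t_runs",
    "pol3_report",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC motif searched over a window of transcript-relative start
    offsets (negative = upstream of the precursor start)."""

    name: str
    iupac: str
    window: tuple[int, int]  # inclusive range of allowed motif START offsets
    max_mismatches: int = 1

    def __post_init__(self):
        if not self.iupac:
            raise ValueError(f"{self.name}: empty motif")
        if self.window[1] < self.window[0]:
            raise ValueError(f"{self.name}: window bounds out of order")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code {sorted(bad)[0]}")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifHit:
    offset: int  # transcript-relative motif start
    matched: str
    mismatches: int


@dataclass(frozen=True)
class TRun:
    offset: int  # relative to 3p-arm 3' end (0 = first nt downstream)
    length: int
    strong: bool  # run length >= 5


def scan_iupac(seq: str, motif: MotifDef) -> list[tuple[int, int]]:
    """All (offset, mismatches) where the motif matches with tolerance.

    ``seq`` is the sense-strand scan window covering start offsets
    ``window[0] .. window[1]``, i.e. it must be at least
    ``window[1] - window[0] + len(motif)`` long.  Results are sorted by
    (mismatches, distance of the offset from the window centre).
    """
    lo, hi = motif.window
    m = len(motif)
    n_starts = hi - lo + 1
    if len(seq) < n_starts + m - 1 or m > len(seq):
        raise ValueError(
            f"{motif.name}: motif ({m} nt) does not fit scan window "
            f"[{lo},{hi}] given sequence of length {len(seq)}"
        )
    pattern = [IUPAC[c] for c in motif.iupac.upper()]
    seq = seq.upper()
    hits = []
    for pos in range(n_starts):
        window = seq[pos : pos + m]
        mism = sum(1 for ch, allowed in zip(window, pattern) if ch not in allowed)
        if mism <= motif.max_mismatches:
            hits.append((lo + pos, mism))
    center = (lo + hi) / 2.0
    hits.sort(key=lambda h: (h[1], abs(h[0] - center)))
    return hits


def find_t_runs(seq: str, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal T runs of length >= min_len as (offset, run_length), left to right."""
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(r"T+", seq.upper().replace("U", "T"))
        if m.end() - m.start() >= min_len
    ]


@dataclass(frozen=True)
class ScanConfig:
    box_a: MotifDef = field(
        default_factory=lambda: MotifDef("BoxA", "TRGCNNARYNNG", (-95, -70), 1)
    )
    box_b: MotifDef = field(
        default_factory=lambda: MotifDef("BoxB", "GWTCRANNC", (-50, -28), 1)
    )
    term_min_run: int = 4
    term_strong_run: int = 5
    proximal_max_gap: int = 10   # T run must start within this many nt of arm end
    distal_max_gap: int = 60     # second run must start within this many nt
    downstream_scan: int = 80
    estimate_tss: bool = True


@dataclass(frozen=True)
class PolIIIReport:
    locus_id: str
    boxA_hit: MotifHit | None
    boxB_hit: MotifHit | None
    proximal_terminator: TRun | None
    distal_terminator: TRun | None
    tss_estimate: int | None  # heuristic (Box A offset - 15); never RACE-grade
    pol3_architecture: bool


def _best_hit(seq: str, motif: MotifDef) -> MotifHit | None:
    hits = scan_iupac(seq, motif)
    if not hits:
        return None
    off, mism = hits[0]
    rel = off - motif.window[0]
    return MotifHit(offset=off, matched=seq[rel : rel + len(motif)], mismatches=mism)


def pol3_report(locus: Locus, genome: GenomeSeq, config: ScanConfig | None = None) -> PolIIIReport:
    """Scan one locus for Box A / Box B / terminator architecture.

    The architecture call requires a Box A hit, a Box B hit, and a
    proximal terminator run; the distal run and TSS estimate are reported
    as corroborating detail only.
    """
    cfg = config or ScanConfig()

    def window_seq(motif: MotifDef) -> str:
        lo, hi = motif.window
        return sense_slice(genome, locus, lo, hi + len(motif))

    boxA = _best_hit(window_seq(cfg.box_a), cfg.box_a)
    boxB = _best_hit(window_seq(cfg.box_b), cfg.box_b)

    if locus.arm3p is not None:
        arm_end = arm_transcript_span(locus, "3p")[1]
    else:
        arm_end = len(locus.precursor)
    down = sense_slice(genome, locus, arm_end, arm_end + cfg.downstream_scan)
    runs = [
        TRun(off, length, length >= cfg.term_strong_run)
        for off, length in find_t_runs(down, cfg.term_min_run)
    ]
    proximal = next((r for r in runs if r.offset <= cfg.proximal_max_gap), None)
    distal = None
    if proximal is not None:
        distal = next(
            (r for r in runs if r.offset > proximal.offset + proximal.length
             and r.offset <= cfg.distal_max_gap),
            None,
        )

    tss = None
    if cfg.estimate_tss and boxA is not None:
        tss = boxA.offset - 15

    return PolIIIReport(
        locus_id=locus.locus_id,
        boxA_hit=boxA,
        boxB_hit=boxB,
        proximal_terminator=proximal,
        distal_terminator=distal,
        tss_estimate=tss,
        pol3_architecture=boxA is not None and boxB is not None and proximal is not None,
    )
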