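"""Read-to-arm assignment, untemplated 3' tail calling, and isoform tables.

A read is decomposed into a templated body and an untemplated 3' tail by
maximizing the templated prefix against the genomic sense sequence extended
downstream past the annotated arm end.  A 3' addition identical to the
genomic downstream base is therefore NOT called untemplated: without
molecular barcodes that ambiguity is undecidable, and the conservative
convention (undercounting tails that mimic the genome) is standard.

The 3p-versus-5p tailing asymmetry statistic operationalizes the
precursor-substrate signature: an enzyme acting on precursor hairpins can
only reach 3p-arm 3' ends, so tailing skewed toward 3p-derived strands
points at precursor-level modification rather than mature-miRNA
modification.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeSeq,
    Locus,
    ReadEntry,
    ValidationError,
    arm_transcript_span,
    sense_slice,
)

__all__ = [
    "ArmIndex",
    "Assignment",
    "TailCall",
    "TailingProfile",
    "AsymmetryStat",
    "assign_read",
    "call_tail",
    "call_tails",
    "tailing_profile",
    "average_profiles",
    "asymmetry_test",
]

TAIL_CLASSES = ("A", "U", "C", "G", "other")


@dataclass(frozen=True)
class Assignment:
    arm_id: str
    start_offset: int  # read 5' start relative to annotated arm 5' end
    weight: float


@dataclass
class ArmIndex:
    """Anchor-prefix index over all annotated arms.

    A read is assignable to an arm when its first ``anchor_len``
    nucleotides match the arm's sense sequence starting within
    ±``start_slop`` nt of the annotated arm 5' end.  Reads matching k arms
    receive fractional weight 1/k each (the htseq ``--nonunique fraction``
    convention).
    """

    anchor_len: int = 16
    start_slop: int = 2
    max_ext: int = 10  # genomic extension past the arm 3' end for tail calling
    _prefix: dict = field(default_factory=dict, repr=False)
    _arms: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, loci: list[Locus], genomes: dict[str, GenomeSeq],
              anchor_len: int = 16, start_slop: int = 2, max_ext: int = 10) -> "ArmIndex":
        idx = cls(anchor_len=anchor_len, start_slop=start_slop, max_ext=max_ext)
        for locus in loci:
            genome = genomes[locus.contig_id]
            for which in ("5p", "3p"):
                if locus.arm(which) is None:
                    continue
                a, b = arm_transcript_span(locus, which)
                arm_id = locus.arm_id(which)
                try:
                    ext = sense_slice(genome, locus, a - start_slop, b + max_ext)
                except ValidationError:
                    ext = sense_slice(genome, locus, a, b)  # clipped at contig edge
                    start_slop_here = 0
                else:
                    start_slop_here = start_slop
                idx._arms[arm_id] = {
                    "ext_seq": ext,
                    "slop": start_slop_here,
                    "arm_len": b - a,
                }
                for off in range(-start_slop_here, start_slop_here + 1):
                    rel = off + start_slop_here
                    anchor = ext[rel : rel + anchor_len]
                    if len(anchor) == anchor_len:
                        idx._prefix.setdefault(anchor, []).append((arm_id, off))
        return idx

    def extended_reference(self, arm_id: str, start_offset: int) -> str:
        info = self._arms[arm_id]
        rel = start_offset + info["slop"]
        return info["ext_seq"][rel:]

    def arm_len(self, arm_id: str) -> int:
        return self._arms[arm_id]["arm_len"]


def assign_read(read: str, index: ArmIndex) -> list[Assignment]:
    """Assign a read to arms by anchored prefix match (empty = unassigned)."""
    if len(read) < index.anchor_len:
        return []
    matches = index._prefix.get(read[: index.anchor_len].upper(), [])
    by_arm: dict[str, int] = {}
    for arm_id, off in matches:
        if arm_id not in by_arm or abs(off) < abs(by_arm[arm_id]):
            by_arm[arm_id] = off
    if not by_arm:
        return []
    w = 1.0 / len(by_arm)
    return [Assignment(a, o, w) for a, o in sorted(by_arm.items())]


@dataclass(frozen=True)
class TailCall:
    read_sequence: str
    arm_id: str
    sample_id: str
    weight: float  # assignment weight x copy number
    templated_length: int
    trim_offset: int  # templated 3' end minus annotated arm 3' end (capped at +3)
    tail: str
    tail_class: str  # none / A / U / C / G / other
    low_confidence: bool = False


def _classify_tail(tail: str) -> str:
    if not tail:
        return "none"
    rna = tail.replace("T", "U")
    if len(set(rna)) == 1 and rna[0] in "AUCG":
        return rna[0]
    return "other"


def call_tail(
    read: str,
    assignment: Assignment,
    index: ArmIndex,
    sample_id: str = "",
    copy_number: int = 1,
    max_tail: int = 5,
) -> TailCall:
    """Split a read into maximal templated prefix + untemplated 3' tail.

    ``templated_length`` is the longest read prefix matching the genomic
    sense sequence extended past the annotated arm end; ``trim_offset`` is
    the templated 3' end relative to the annotated arm 3' end (<= 0 for
    trimming isoforms; templated extensions are reported capped at +3).
    Tails longer than ``max_tail`` are flagged low-confidence.
    """
    read = read.upper()
    ref = index.extended_reference(assignment.arm_id, assignment.start_offset)
    t = 0
    limit = min(len(read), len(ref))
    while t < limit and read[t] == ref[t]:
        t += 1
    if t < index.anchor_len:
        raise ValidationError(
            f"read does not match {assignment.arm_id} over the anchor; "
            "inconsistent assignment"
        )
    tail = read[t:]
    trim = (assignment.start_offset + t) - index.arm_len(assignment.arm_id)
    return TailCall(
        read_sequence=read,
        arm_id=assignment.arm_id,
        sample_id=sample_id,
        weight=assignment.weight * copy_number,
        templated_length=t,
        trim_offset=min(trim, 3),
        tail=tail,
        tail_class=_classify_tail(tail),
        low_confidence=len(tail) > max_tail,
    )


def call_tails(entries: list[ReadEntry], index: ArmIndex, max_tail: int = 5) -> list[TailCall]:
    """Assign and tail-call a collapsed read set (all samples pooled in)."""
    calls: list[TailCall] = []
    for e in entries:
        for asn in assign_read(e.sequence, index):
            calls.append(
                call_tail(e.sequence, asn, index, sample_id=e.sample_id,
                          copy_number=e.copy_number, max_tail=max_tail)
            )
    return calls


@dataclass
class TailingProfile:
    arm_id: str
    total_reads: float  # weighted
    pct: dict  # tail class -> percent of reads, incl. "none"
    isoform_table: dict  # (trim_offset, tail_class) -> weighted count
    top_isoforms: list  # top-k (trim_offset, tail_class, count)
    rpm: float

    def pct_tailed(self, nucleotide: str) -> float:
        return self.pct.get(nucleotide, 0.0)


def tailing_profile(
    calls: list[TailCall],
    min_rpm: float = 1.0,
    top_k: int = 6,
) -> dict[str, TailingProfile]:
    """Per-arm tailing/isoform profiles for one sample's calls.

    RPM is computed over all assigned (weighted) reads in the sample; arms
    below ``min_rpm`` are excluded from the report.  The isoform table is
    keyed by (trim offset, tail class) and the ``top_k`` most abundant
    isoforms are surfaced separately.
    """
    if not calls:
        return {}
    by_arm: dict[str, list[TailCall]] = defaultdict(list)
    for c in calls:
        by_arm[c.arm_id].append(c)
    grand_total = sum(c.weight for c in calls)
    out: dict[str, TailingProfile] = {}
    for arm_id, arm_calls in sorted(by_arm.items()):
        total = sum(c.weight for c in arm_calls)
        rpm = total / grand_total * 1e6 if grand_total > 0 else 0.0
        if rpm < min_rpm:
            continue
        pct = {cls: 0.0 for cls in ("none",) + TAIL_CLASSES}
        iso: dict[tuple[int, str], float] = defaultdict(float)
        for c in arm_calls:
            pct[c.tail_class] += c.weight
            iso[(c.trim_offset, c.tail_class)] += c.weight
        pct = {k: 100.0 * v / total for k, v in pct.items()}
        top = sorted(iso.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        out[arm_id] = TailingProfile(
            arm_id=arm_id,
            total_reads=total,
            pct=pct,
            isoform_table=dict(iso),
            top_isoforms=[(t, cls, n) for (t, cls), n in top],
            rpm=rpm,
        )
    return out


def average_profiles(per_sample: list[dict[str, TailingProfile]]) -> dict[str, TailingProfile]:
    """Equal-weight average of per-sample profiles (figure-style output).

    Arms are averaged over the samples in which they passed the abundance
    filter; isoform tables are summed.
    """
    arms = sorted({a for prof in per_sample for a in prof})
    out: dict[str, TailingProfile] = {}
    for arm in arms:
        profs = [p[arm] for p in per_sample if arm in p]
        pct = {
            cls: float(np.mean([pr.pct.get(cls, 0.0) for pr in profs]))
            for cls in ("none",) + TAIL_CLASSES
        }
        iso: dict[tuple[int, str], float] = defaultdict(float)
        for pr in profs:
            for k, v in pr.isoform_table.items():
                iso[k] += v
        top = sorted(iso.items(), key=lambda kv: (-kv[1], kv[0]))[:6]
        out[arm] = TailingProfile(
            arm_id=arm,
            total_reads=float(np.mean([pr.total_reads for pr in profs])),
            pct=pct,
            isoform_table=dict(iso),
            top_isoforms=[(t, cls, n) for (t, cls), n in top],
            rpm=float(np.mean([pr.rpm for pr in profs])),
        )
    return out


@dataclass(frozen=True)
class AsymmetryStat:
    delta: float  # mean %tail over 3p arms minus mean over 5p arms
    permutation_p: float
    nucleotide: str
    n_3p: int
    n_5p: int


def asymmetry_test(
    profiles: dict[str, TailingProfile],
    nucleotide: str = "A",
    n_perm: int = 10000,
    seed: int = 0,
) -> AsymmetryStat:
    """Permutation test for 3p-vs-5p tailing skew of one nucleotide class.

    delta = mean(%tail over 3p arms) - mean(%tail over 5p arms); the p
    value is the add-one-corrected fraction of arm-label permutations with
    |delta| at least as large as observed.
    """
    vals_3p = [p.pct_tailed(nucleotide) for a, p in profiles.items() if a.endswith("_3p")]
    vals_5p = [p.pct_tailed(nucleotide) for a, p in profiles.items() if a.endswith("_5p")]
    if len(vals_3p) < 2 or len(vals_5p) < 2:
        raise ValidationError("need >= 2 arms on each strand class for the test")
    delta = float(np.mean(vals_3p) - np.mean(vals_5p))
    pooled = np.array(vals_3p + vals_5p)
    n3 = len(vals_3p)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n3].mean() - perm[n3:].mean()
        if abs(d) >= abs(delta) - 1e-12:
            count += 1
    return AsymmetryStat(
        delta=delta,
        permutation_p=(1 + count) / (n_perm + 1),
        nucleotide=nucleotide,
        n_3p=n3,
        n_5p=len(vals_5p),
    )
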