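"""Rule-based integration of depletion, structure, promoter and tailing
evidence into biogenesis-class labels, plus the Microprocessor
cleavage-efficiency score.

The label set distinguishes canonical (Microprocessor- and
Dicer-dependent) miRNAs from splicing-derived mirtron-like loci, Pol
III-transcribed Dicer-dependent noncanonical miRNAs, Pol III products
needing neither Microprocessor nor Dicer, and small RNAs misannotated as
miRNAs (21-nt 5'U piRNAs; 26-nt 5'G endo-siRNAs).  Rules are evaluated in
a fixed priority order and every fired/failed predicate is recorded in the
rationale, so each call is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import Interval, Locus

__all__ = [
    "CleavageScore",
    "EvidenceVector",
    "ClassLabel",
    "Thresholds",
    "cleavage_score",
    "chip_overlap",
    "classify_locus",
]

LABELS = (
    "canonical",
    "mirtron_like",
    "polIII_noncanonical",
    "mp_dicer_independent",
    "misannotated_piRNA",
    "misannotated_26G",
    "unclassified",
)


@dataclass(frozen=True)
class CleavageScore:
    """log2(products + 0.1) - log2(substrates + 0.1) on normalized counts."""

    score: float
    n_product: float
    n_substrate: float


def cleavage_score(n_product: float, n_substrate: float) -> CleavageScore:
    """Microprocessor cleavage-efficiency score with the 0.1 offset.

    Equal product and substrate abundance scores 0; complete conversion of
    detectable substrate into product gives large positive scores.
    """
    if n_product < 0 or n_substrate < 0:
        raise ValueError("normalized counts must be non-negative")
    score = math.log2(n_product + 0.1) - math.log2(n_substrate + 0.1)
    return CleavageScore(score=score, n_product=n_product, n_substrate=n_substrate)


def chip_overlap(
    loci: list[Locus], peaks: list[tuple[str, int, int]]
) -> dict[str, bool]:
    """Per-locus: does the precursor intersect any peak by >= 1 bp?

    Intervals are half-open; a peak on a contig absent from the
    annotation simply never overlaps (no error).
    """
    by_contig: dict[str, list[Interval]] = {}
    for contig, start, end in peaks:
        by_contig.setdefault(contig, []).append(Interval(start, end))
    return {
        loc.locus_id: any(
            loc.precursor.overlaps(p) for p in by_contig.get(loc.contig_id, [])
        )
        for loc in loci
    }


@dataclass(frozen=True)
class Thresholds:
    dicer_lfc: float = -1.0
    dicer_p_adj: float = 0.05
    pol3_lfc: float = -1.0
    pol3_p_adj: float = 0.05
    mp_insensitive_lfc: float = -0.5  # insensitive iff lfc >= this in a dataset
    pirna_length: int = 21
    sirna26g_length: int = 26


@dataclass(frozen=True)
class EvidenceVector:
    locus_id: str
    lfc_MP_1: float | None = None
    lfc_MP_2: float | None = None
    lfc_dicer: float | None = None
    p_adj_dicer: float | None = None
    lfc_polIII: float | None = None
    p_adj_polIII: float | None = None
    short_hairpin: bool | None = None
    polIII_architecture: bool = False
    chip_overlap: bool = False
    dominant_length: int | None = None
    first_nt: str | None = None  # RNA alphabet: A/C/G/U
    a_tail_3p_bias: bool = False


@dataclass(frozen=True)
class ClassLabel:
    locus_id: str
    label: str
    rationale: tuple[str, ...]


def _sig_down(lfc, p_adj, lfc_cut, p_cut) -> bool:
    return lfc is not None and p_adj is not None and lfc <= lfc_cut and p_adj < p_cut


def classify_locus(ev: EvidenceVector, thresholds: Thresholds | None = None) -> ClassLabel:
    """Assign exactly one biogenesis class by priority-ordered rules.

    Priority: misannotated piRNA > misannotated 26G > Pol III
    MP/Dicer-independent > Pol III noncanonical > mirtron-like > canonical
    > unclassified.  MP insensitivity must hold in every available MP
    dataset (conjunction); with a single dataset the rule degrades to that
    dataset alone and the rationale says so.
    """
    th = thresholds or Thresholds()
    r: list[str] = []

    mp_lfcs = [x for x in (ev.lfc_MP_1, ev.lfc_MP_2) if x is not None]
    has_any = bool(mp_lfcs) or ev.lfc_dicer is not None or ev.lfc_polIII is not None
    if not has_any and ev.dominant_length is None:
        return ClassLabel(ev.locus_id, "unclassified", ("no data",))

    if mp_lfcs:
        mp_insensitive = all(x >= th.mp_insensitive_lfc for x in mp_lfcs)
        n = len(mp_lfcs)
        r.append(
            f"MP {'in' if mp_insensitive else ''}sensitive in {n} dataset(s) "
            f"(lfc {[round(x, 3) for x in mp_lfcs]} vs threshold {th.mp_insensitive_lfc})"
            + ("; single MP dataset only" if n == 1 else "")
        )
    else:
        mp_insensitive = None
        r.append("no MP evidence")

    dicer_dep = _sig_down(ev.lfc_dicer, ev.p_adj_dicer, th.dicer_lfc, th.dicer_p_adj)
    r.append(
        f"dicer_dependent={dicer_dep} (lfc={ev.lfc_dicer}, p_adj={ev.p_adj_dicer})"
    )
    pol3_dep = _sig_down(ev.lfc_polIII, ev.p_adj_polIII, th.pol3_lfc, th.pol3_p_adj)
    pol3_evidence = pol3_dep or (ev.polIII_architecture and ev.chip_overlap)
    r.append(
        f"polIII_dependent={pol3_dep}, architecture={ev.polIII_architecture}, "
        f"chip={ev.chip_overlap}"
    )

    # (1) misannotated piRNA: 21 nt, 5'U, not Dicer-dependent
    if (
        ev.dominant_length == th.pirna_length
        and ev.first_nt == "U"
        and not dicer_dep
    ):
        r.append(f"{th.pirna_length} nt with 5'U and Dicer-independent")
        return ClassLabel(ev.locus_id, "misannotated_piRNA", tuple(r))
    # (2) misannotated 26G endo-siRNA: 26 nt, 5'G
    if ev.dominant_length == th.sirna26g_length and ev.first_nt == "G":
        r.append(f"{th.sirna26g_length} nt with 5'G")
        return ClassLabel(ev.locus_id, "misannotated_26G", tuple(r))
    # (3) Pol III product needing neither MP nor Dicer
    if mp_insensitive and not dicer_dep and (pol3_dep or ev.polIII_architecture):
        r.append("MP-insensitive, Dicer-independent, Pol III evidence")
        return ClassLabel(ev.locus_id, "mp_dicer_independent", tuple(r))
    # (4) Pol III-dependent, MP-independent, Dicer-dependent
    if mp_insensitive and dicer_dep and pol3_evidence:
        r.append("MP-insensitive, Dicer-dependent, Pol III evidence")
        return ClassLabel(ev.locus_id, "polIII_noncanonical", tuple(r))
    # (5) mirtron-like: MP-independent short hairpin without Pol III evidence
    if mp_insensitive and dicer_dep and bool(ev.short_hairpin) and not pol3_evidence:
        r.append("MP-insensitive, Dicer-dependent, short hairpin, no Pol III evidence")
        return ClassLabel(ev.locus_id, "mirtron_like", tuple(r))
    # (6) canonical: MP-sensitive and Dicer-dependent
    if mp_insensitive is False and dicer_dep:
        r.append("MP-sensitive and Dicer-dependent")
        return ClassLabel(ev.locus_id, "canonical", tuple(r))
    r.append("no rule satisfied")
    return ClassLabel(ev.locus_id, "unclassified", tuple(r))
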