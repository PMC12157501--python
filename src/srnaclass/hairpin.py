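"""Hairpin structural classification.

Stem length here is the COUNT OF BASE PAIRS whose partners both lie inside
the precursor span, not a nucleotide span: canonical animal pre-miRNA
hairpins carry ~35 pairs including a basal stem, while splicing-derived
mirtrons and other Microprocessor-independent precursors fall short of the
32-pair boundary used for the "short hairpin" call.

Structures normally come from an external thermodynamic folder via
dot-bracket files; :func:`fold_maxpair` is the built-in base-pair-maximising
(Nussinov) fallback so the pipeline runs with zero external tools, and it
doubles as an exhaustively checkable oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Locus

__all__ = [
    "StructureError",
    "HairpinReport",
    "parse_dotbracket",
    "fold_maxpair",
    "hairpin_report",
]

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


class StructureError(ValueError):
    pass


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or GU wobble; T and U are equivalent."""
    return (a.replace("U", "T"), b.replace("U", "T")) in _PAIRABLE


def parse_dotbracket(struct: str) -> list[tuple[int, int]]:
    """Stack-match a dot-bracket string into (open, close) index pairs.

    Pairs are returned sorted by opening index.  Unbalanced structures
    raise :class:`StructureError` naming the offending position.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(struct):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise StructureError(
            f"unmatched '(' at position {stack[-1]} (end of string reached)"
        )
    return sorted(pairs)


def fold_maxpair(seq: str, min_loop: int = 3) -> str:
    """Base-pair-maximising nested fold (Nussinov recursion).

    Maximises the number of Watson-Crick + GU pairs subject to nesting and
    a hairpin loop of at least ``min_loop`` unpaired nucleotides.  Ties are
    broken by preferring the pair with the smaller opening index during
    traceback, which makes the returned structure deterministic.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return ""
    enc = np.frombuffer(s.encode(), dtype=np.uint8)
    pairable = np.zeros((n, n), dtype=bool)
    code = {65: "A", 67: "C", 71: "G", 84: "T"}
    for i in range(n):
        a = code.get(enc[i])
        if a is None:
            continue
        for j in range(i + min_loop + 1, n):
            b = code.get(enc[j])
            if b is not None and (a, b) in _PAIRABLE:
                pairable[i, j] = True

    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # M[i, j] over span [i, j-1]

    def score(i: int, j: int) -> int:  # inclusive indices
        return M[i, j + 1] if i <= j else 0

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = score(i, j - 1)  # j unpaired
            ks = np.nonzero(pairable[i : j - min_loop, j])[0]
            for k0 in ks:
                k = i + int(k0)
                cand = score(i, k - 1) + 1 + score(k + 1, j - 1)
                if cand > best:
                    best = cand
            M[i, j + 1] = best

    struct = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i <= j:
            target = score(i, j)
            if target == 0:
                return
            done = False
            for k in range(i, j - min_loop):
                if pairable[k, j] and score(i, k - 1) + 1 + score(k + 1, j - 1) == target:
                    struct[k] = "("
                    struct[j] = ")"
                    traceback(i, k - 1)
                    i, j = k + 1, j - 1
                    done = True
                    break
            if not done:
                j -= 1  # j unpaired

    traceback(0, n - 1)
    return "".join(struct)


@dataclass(frozen=True)
class HairpinReport:
    locus_id: str
    structure: str
    stem_pairs: int
    short_hairpin: bool
    unpaired_5p_flank: int
    unpaired_3p_flank: int


def hairpin_report(
    locus: Locus,
    struct: str,
    threshold: int = 32,
    precursor_span: tuple[int, int] | None = None,
) -> HairpinReport:
    """Count precursor-internal base pairs and apply the short-hairpin rule.

    ``struct`` must cover the precursor; when it covers a larger window,
    ``precursor_span`` gives the precursor's [start, end) within it.  A
    hairpin is called "short" when fewer than ``threshold`` pairs lie fully
    inside the precursor (default 32).  Flank-unpaired counts are the
    contiguous unpaired runs measured inward from the precursor termini.
    """
    plen = len(locus.precursor)
    if precursor_span is None:
        if len(struct) != plen:
            raise StructureError(
                f"{locus.locus_id}: structure length {len(struct)} != precursor "
                f"length {plen}"
            )
        span = (0, len(struct))
    else:
        span = precursor_span
        if span[1] - span[0] != plen or span[0] < 0 or span[1] > len(struct):
            raise StructureError(
                f"{locus.locus_id}: precursor span {span} inconsistent with "
                f"structure of length {len(struct)}"
            )
    pairs = parse_dotbracket(struct)
    a, b = span
    stem_pairs = sum(1 for i, j in pairs if a <= i and j < b)

    inner = struct[a:b]
    up5 = len(inner) - len(inner.lstrip("."))
    up3 = len(inner) - len(inner.rstrip("."))
    return HairpinReport(
        locus_id=locus.locus_id,
        structure=struct,
        stem_pairs=stem_pairs,
        short_hairpin=stem_pairs < threshold,
        unpaired_5p_flank=up5,
        unpaired_3p_flank=up3,
    )
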