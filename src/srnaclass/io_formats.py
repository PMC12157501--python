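"""Readers/writers for every external representation the pipeline touches.

Coordinate conventions
----------------------
All internal intervals are 0-based, half-open ``[start, end)`` on the
genomic forward strand.  GFF3 (1-based, closed) is converted at the I/O
boundary.  Per-locus sequence is always extracted on the SENSE (transcript)
strand: minus-strand loci are reverse-complemented at extraction, so
transcript-relative offsets (promoter elements upstream, terminators
downstream) mean the same thing on both strands.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomeSeq",
    "Interval",
    "Locus",
    "CountMatrix",
    "ReadEntry",
    "revcomp",
    "sense_slice",
    "arm_transcript_span",
    "read_fasta",
    "write_fasta",
    "read_loci_gff3",
    "write_loci_gff3",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_collapsed_fasta",
    "write_collapsed_fasta",
    "read_dotbracket",
    "write_dotbracket",
    "read_bed",
    "write_bed",
]

GENOME_ALPHABET = set("ACGTN")
READ_ALPHABET = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSeq:
    contig_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r}: invalid character {sorted(bad)[0]}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"empty/inverted interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Locus:
    """An annotated small-RNA gene: precursor plus optional 5p/3p arms.

    Arm names are transcript-orientation: on the minus strand the 5p arm
    has the larger genomic coordinates.
    """

    locus_id: str
    contig_id: str
    strand: str
    precursor: Interval
    arm5p: Interval | None = None
    arm3p: Interval | None = None
    host_gene_id: str | None = None

    min_precursor_len: int = field(default=40, repr=False, compare=False)
    max_precursor_len: int = field(default=200, repr=False, compare=False)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.locus_id}: unknown strand {self.strand!r}")
        plen = len(self.precursor)
        if not (self.min_precursor_len <= plen <= self.max_precursor_len):
            raise ValidationError(
                f"{self.locus_id}: precursor length {plen} outside "
                f"[{self.min_precursor_len},{self.max_precursor_len}]"
            )
        for name, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if arm is not None and not self.precursor.contains(arm):
                raise ValidationError(
                    f"{self.locus_id}: {name} {arm} outside precursor {self.precursor}"
                )
        if self.arm5p is not None and self.arm3p is not None:
            if self.strand == "+" and self.arm5p.start >= self.arm3p.start:
                raise ValidationError(f"{self.locus_id}: arm5p must precede arm3p")
            if self.strand == "-" and self.arm5p.start <= self.arm3p.start:
                raise ValidationError(
                    f"{self.locus_id}: arm5p must precede arm3p in transcript orientation"
                )

    def arm(self, which: str) -> Interval | None:
        return self.arm5p if which == "5p" else self.arm3p

    def arm_id(self, which: str) -> str:
        return f"{self.locus_id}_{which}"


def sense_slice(genome: GenomeSeq, locus: Locus, rel_start: int, rel_end: int) -> str:
    """Sense-strand sequence of a transcript-relative interval.

    Offset 0 is the precursor start in transcript orientation; negative
    offsets are upstream (promoter side), offsets past the precursor
    length are downstream (terminator side).
    """
    if rel_end <= rel_start:
        raise ValueError("rel_end must exceed rel_start")
    prec = locus.precursor
    if locus.strand == "+":
        g0, g1 = prec.start + rel_start, prec.start + rel_end
    else:
        g0, g1 = prec.end - rel_end, prec.end - rel_start
    if g0 < 0 or g1 > len(genome):
        raise ValidationError(
            f"{locus.locus_id}: window [{rel_start},{rel_end}) falls off contig "
            f"{genome.contig_id!r}"
        )
    seq = genome.sequence[g0:g1]
    return revcomp(seq) if locus.strand == "-" else seq


def arm_transcript_span(locus: Locus, which: str) -> tuple[int, int]:
    """Transcript-relative [start, end) of an arm, 0 = precursor start."""
    arm = locus.arm(which)
    if arm is None:
        raise ValueError(f"{locus.locus_id}: no {which} arm")
    prec = locus.precursor
    if locus.strand == "+":
        return arm.start - prec.start, arm.end - prec.start
    return prec.end - arm.end, prec.end - arm.start


# ---------------------------------------------------------------------------
# FASTA

def _fasta_error_line(path, record_id: str, offending: str) -> int:
    """Locate the 1-based line of the first offending character in a record."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and offending in line.upper():
                return lineno
    return -1


def read_fasta(path) -> list[GenomeSeq]:
    """Read a FASTA file into genome records (uppercased, alphabet-checked)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - GENOME_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            line = _fasta_error_line(path, rec.id, ch)
            raise FormatError(f"{path}: invalid character {ch} at line {line}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records.append(GenomeSeq(rec.id, seq))
    return records


def write_fasta(path, records: list[GenomeSeq], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 loci

def _parse_gff3_attrs(attrs: str) -> dict:
    out = {}
    for part in attrs.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_loci_gff3(path, min_precursor_len: int = 40, max_precursor_len: int = 200) -> list[Locus]:
    """Read pre_miRNA records with child miRNA arm records from GFF3.

    GFF3 coordinates are 1-based closed; internal intervals are 0-based
    half-open (``[s-1, e)``).  Children attach to parents via ID/Parent;
    the arm role is taken from an ``arm=5p|3p`` attribute, or inferred
    from a ``-5p``/``-3p`` suffix on the child's ID or Name.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    loci: list[Locus] = []
    for pre in db.features_of_type("pre_miRNA", order_by="start"):
        if pre.strand not in ("+", "-"):
            raise ValidationError(f"{pre.id}: unknown strand {pre.strand!r}")
        prec = Interval(pre.start - 1, pre.end)
        arms: dict[str, Interval] = {}
        host = pre.attributes.get("host_gene", [None])[0]
        for child in db.children(pre, featuretype="miRNA", order_by="start"):
            which = child.attributes.get("arm", [None])[0]
            if which is None:
                name = (child.attributes.get("Name", [child.id])[0] or child.id)
                for suffix in ("5p", "3p"):
                    if name.endswith(suffix):
                        which = suffix
            if which not in ("5p", "3p"):
                raise ValidationError(
                    f"{pre.id}: cannot determine arm role for child {child.id!r}"
                )
            ivl = Interval(child.start - 1, child.end)
            if not prec.contains(ivl):
                raise ValidationError(
                    f"{pre.id}: {which} arm {ivl} outside precursor {prec}"
                )
            arms[which] = ivl
        loci.append(
            Locus(
                locus_id=pre.id,
                contig_id=pre.seqid,
                strand=pre.strand,
                precursor=prec,
                arm5p=arms.get("5p"),
                arm3p=arms.get("3p"),
                host_gene_id=host,
                min_precursor_len=min_precursor_len,
                max_precursor_len=max_precursor_len,
            )
        )
    return loci


def write_loci_gff3(path, loci: list[Locus]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.locus_id}"
            if loc.host_gene_id:
                attrs += f";host_gene={loc.host_gene_id}"
            fh.write(
                "\t".join(
                    [
                        loc.contig_id, "srnaclass", "pre_miRNA",
                        str(loc.precursor.start + 1), str(loc.precursor.end),
                        ".", loc.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for which in ("5p", "3p"):
                arm = loc.arm(which)
                if arm is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            loc.contig_id, "srnaclass", "miRNA",
                            str(arm.start + 1), str(arm.end),
                            ".", loc.strand, ".",
                            f"ID={loc.arm_id(which)};Parent={loc.locus_id};arm={which}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Count matrices

@dataclass
class CountMatrix:
    """samples x features counts with per-sample spike-in totals.

    ``counts`` is a features-by-samples DataFrame (may be fractional when
    reads were assigned with a nonunique-fraction convention);
    ``spike_counts``/``condition`` are Series indexed by sample id.
    """

    counts: pd.DataFrame
    spike_counts: pd.Series
    condition: pd.Series

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        self.spike_counts = self.spike_counts.reindex(self.counts.columns)
        self.condition = self.condition.reindex(self.counts.columns)
        if self.spike_counts.isna().any() or self.condition.isna().any():
            raise ValidationError("spike_counts/condition missing for some sample")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)].copy(), self.spike_counts.copy(),
                           self.condition.copy())


def _default_condition(sample_id: str) -> str:
    return sample_id.rsplit("_", 1)[0] if "_" in sample_id else sample_id


def read_counts_tsv(path, spike_prefix: str = "spike_", conditions: dict | None = None) -> CountMatrix:
    """Read a feature x sample count TSV, splitting off spike-in rows.

    Rows whose id starts with ``spike_prefix`` are removed from the count
    table and summed into per-sample spike totals.  Conditions come from a
    ``# condition:`` header comment when present, then the ``conditions``
    mapping, then the sample-id prefix before the final underscore.
    """
    cond_from_header = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# condition:"):
            cond_from_header = dict(
                item.split("=", 1) for item in first[len("# condition:"):].strip().split(",") if item
            )
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0, comment="#")
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: no samples found")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count cell")
    is_spike = df.index.astype(str).str.startswith(spike_prefix)
    if not is_spike.any():
        raise FormatError(
            f"{path}: no features match spike prefix {spike_prefix!r}; "
            "cannot compute spike-in size factors"
        )
    spikes = df.loc[is_spike].sum(axis=0)
    if (spikes <= 0).any():
        bad = list(spikes.index[spikes <= 0])
        raise ValidationError(
            f"samples {bad} have zero spike-in total; disable spike normalization "
            "or drop these samples"
        )
    counts = df.loc[~is_spike]
    cond_map = cond_from_header or conditions or {}
    cond = pd.Series(
        [cond_map.get(s, _default_condition(s)) for s in counts.columns],
        index=counts.columns,
    )
    return CountMatrix(counts=counts, spike_counts=spikes, condition=cond)


def write_counts_tsv(path, cm: CountMatrix, spike_prefix: str = "spike_",
                     spike_split: int = 1) -> None:
    """Write a CountMatrix as TSV with spike totals re-expanded to rows."""
    with open(path, "w") as fh:
        fh.write("# condition:" + ",".join(f"{s}={c}" for s, c in cm.condition.items()) + "\n")
        out = cm.counts.copy()
        # emit spike totals as a single aggregate row (read_counts_tsv re-sums)
        spike_row = cm.spike_counts.rename(f"{spike_prefix}total")
        out = pd.concat([out, spike_row.to_frame().T])
        out.index.name = "feature"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Collapsed reads

@dataclass(frozen=True)
class ReadEntry:
    sequence: str
    copy_number: int
    sample_id: str

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValidationError("copy_number must be >= 1")
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise ValidationError(f"read contains invalid character {sorted(bad)[0]}")


def read_collapsed_fasta(path, sample_id: str, min_len: int = 16, max_len: int = 35) -> list[ReadEntry]:
    """Read collapsed reads from FASTA with ``readN_xCOPY`` headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            copy = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            raise FormatError(
                f"{path}: header {rec.id!r} lacks the _xCOPY copy-number suffix"
            ) from None
        seq = str(rec.seq).upper()
        if not (min_len <= len(seq) <= max_len):
            raise ValidationError(
                f"{path}: read {rec.id!r} length {len(seq)} outside [{min_len},{max_len}]"
            )
        entries.append(ReadEntry(seq, copy, sample_id))
    return entries


def write_collapsed_fasta(path, entries: list[ReadEntry]) -> None:
    with open(path, "w") as fh:
        for i, e in enumerate(entries, start=1):
            fh.write(f">read{i}_x{e.copy_number}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# Dot-bracket structure records (">id\nSEQ\nSTRUCT")

def read_dotbracket(path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header at record starting line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record {lines[i][1:]!r}")
        rid, seq, struct = lines[i][1:].split()[0], lines[i + 1].upper(), lines[i + 2]
        if len(seq) != len(struct):
            raise FormatError(f"{path}: sequence/structure length mismatch for {rid!r}")
        out[rid] = (seq, struct)
        i += 3
    return out


def write_dotbracket(path, records: dict[str, tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, (seq, struct) in records.items():
            fh.write(f">{rid}\n{seq}\n{struct}\n")


# ---------------------------------------------------------------------------
# BED6

def read_bed(path) -> list[tuple[str, int, int]]:
    """Read intervals (contig, start, end) from a BED3+ file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["contig", "start", "end"])
    return [(str(r.contig), int(r.start), int(r.end)) for r in df.itertuples()]


def write_bed(path, rows: list[tuple]) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
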