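"""Genome/annotation/TSS input-output and strand-aware window extraction.

All internal coordinates are 0-based, half-open.  File interfaces keep each
format's native convention (GFF3 is 1-based inclusive).  "Offset 0" of a
translation initiation region (TIR) window is the first nucleotide of the
annotated start codon; offset -1 is the nucleotide immediately 5' of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

GENOME_ALPHABET = frozenset("ACGTN")

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "TIRWindow",
    "TSSRecord",
    "SequenceIOError",
    "ParseError",
    "read_genome",
    "write_genome",
    "read_annotations",
    "write_annotations",
    "read_tss_table",
    "write_tss_table",
    "reverse_complement",
    "transcribe",
    "extract_tir_window",
    "extract_upstream_of_tss",
]


class SequenceIOError(ValueError):
    """Base error for malformed inputs or failed lookups."""


class ParseError(SequenceIOError):
    """A file could not be parsed; the message names the offending record."""


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an uppercase DNA sequence over {A, C, G, T, N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise ParseError(
                f"contig {self.contig_id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS feature in internal 0-based half-open coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise SequenceIOError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SequenceIOError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """A transcriptional start site assigned to a gene, on the gene's strand."""

    gene_id: str
    contig_id: str
    tss_position: int
    strand: str


@dataclass(frozen=True)
class TIRWindow:
    """mRNA-sense RNA window around a start codon.

    ``offset_start`` is the offset of the first stored base; offsets run
    contiguously.  ``complete`` is False when the requested range was clipped
    at a contig edge (the sequence is shortened, offsets preserved).
    """

    gene_id: str
    offset_start: int
    sequence: str
    complete: bool = True

    @property
    def offsets(self) -> range:
        return range(self.offset_start, self.offset_start + len(self.sequence))

    def base_at(self, offset: int) -> str | None:
        """Base at a TIR offset, or None if the offset is not covered."""
        i = offset - self.offset_start
        if 0 <= i < len(self.sequence):
            return self.sequence[i]
        return None

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA (sense strand) to RNA: T becomes U."""
    return seq.replace("T", "U")


def read_genome(path: str | Path) -> dict[str, GenomeRecord]:
    """Read a FASTA file into a contig-keyed mapping.

    Sequences are uppercased and U is converted to T on input.  Duplicate
    contig ids, illegal characters and empty files raise :class:`ParseError`.
    """
    records: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate contig id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        records[rec.id] = GenomeRecord(contig_id=rec.id, sequence=seq)
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_genome(path: str | Path, genomes: Mapping[str, GenomeRecord]) -> None:
    with open(path, "w") as fh:
        for rec in genomes.values():
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_annotations(
    path: str | Path,
    feature_type: str = "CDS",
    id_attribute: str = "locus_tag",
) -> list[GeneAnnotation]:
    """Read gene annotations of one feature type from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  NCBI GFF dialects differ in where the stable gene
    identifier lives, so the attribute key is configurable.
    """
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ParseError(f"{path}:{lineno}: malformed GFF3 line ({exc})")
            if feat.featuretype != feature_type:
                continue
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: unknown strand {feat.strand!r}"
                )
            if feat.end < feat.start:
                raise ParseError(f"{path}:{lineno}: end < start")
            ids = feat.attributes.get(id_attribute, [])
            if not ids:
                raise ParseError(
                    f"{path}:{lineno}: missing {id_attribute!r} attribute"
                )
            gene_id = ids[0]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig_id=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    return out


def write_annotations(
    path: str | Path,
    annotations: Iterable[GeneAnnotation],
    feature_type: str = "CDS",
    id_attribute: str = "locus_tag",
) -> None:
    """Write annotations back out as GFF3 (native 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.contig_id,
                        "tirscope",
                        feature_type,
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        "0",
                        f"{id_attribute}={a.gene_id}",
                    ]
                )
                + "\n"
            )


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table (TSV: gene_id, contig, position, strand).

    The header line may be prefixed with '#' (our writers emit it that way).
    Positions are 0-based.
    """
    records: list[TSSRecord] = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        names = header.split("\t")
        required = {"gene_id", "contig", "position", "strand"}
        if not required <= set(names):
            raise ParseError(f"{path}: TSS header must contain {sorted(required)}")
        idx = {n: i for i, n in enumerate(names)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                records.append(
                    TSSRecord(
                        gene_id=parts[idx["gene_id"]],
                        contig_id=parts[idx["contig"]],
                        tss_position=int(parts[idx["position"]]),
                        strand=parts[idx["strand"]],
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad TSS row ({exc})")
    return records


def write_tss_table(path: str | Path, records: Iterable[TSSRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tcontig\tposition\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.contig_id}\t{r.tss_position}\t{r.strand}\n")


def _get_contig(genomes: Mapping[str, GenomeRecord], contig_id: str) -> GenomeRecord:
    try:
        return genomes[contig_id]
    except KeyError:
        raise SequenceIOError(f"contig {contig_id!r} not found in genome")


def extract_tir_window(
    genomes: Mapping[str, GenomeRecord],
    gene: GeneAnnotation,
    upstream: int,
    downstream: int,
) -> TIRWindow:
    """Extract the mRNA-sense RNA window covering offsets [-upstream, +downstream].

    Offsets 0..2 equal the annotated start codon.  Windows crossing a contig
    edge are shortened (never padded) and flagged ``complete=False``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    contig = _get_contig(genomes, gene.contig_id)
    n = len(contig)
    if gene.end > n:
        raise SequenceIOError(
            f"gene {gene.gene_id!r} extends past contig {gene.contig_id!r}"
        )
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream + 1
        clo, chi = max(lo, 0), min(hi, n)
        seq = transcribe(contig.sequence[clo:chi])
        offset_start = clo - gene.start
    else:
        anchor = gene.end - 1  # genomic index of the start codon's first base
        lo, hi = anchor - downstream, anchor + upstream + 1
        clo, chi = max(lo, 0), min(hi, n)
        seq = transcribe(reverse_complement(contig.sequence[clo:chi]))
        offset_start = anchor - (chi - 1)
    return TIRWindow(
        gene_id=gene.gene_id,
        offset_start=offset_start,
        sequence=seq,
        complete=(clo == lo and chi == hi),
    )


def extract_upstream_of_tss(
    genomes: Mapping[str, GenomeRecord],
    tss: TSSRecord,
    n: int,
    as_rna: bool = False,
) -> str:
    """The n nucleotides 5' of (not including) the TSS, on the gene's strand.

    Returned 5'->3' in sense orientation, shortened if a contig edge
    intervenes.  Promoter elements are DNA features, so the default alphabet
    is DNA; pass ``as_rna=True`` for the transcribed string.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    contig = _get_contig(genomes, tss.contig_id)
    length = len(contig)
    if not 0 <= tss.tss_position < length:
        raise SequenceIOError(
            f"TSS for {tss.gene_id!r} at {tss.tss_position} outside contig"
        )
    if tss.strand == "+":
        lo = max(tss.tss_position - n, 0)
        seq = contig.sequence[lo : tss.tss_position]
    elif tss.strand == "-":
        hi = min(tss.tss_position + 1 + n, length)
        seq = reverse_complement(contig.sequence[tss.tss_position + 1 : hi])
    else:
        raise SequenceIOError(f"TSS for {tss.gene_id!r}: unknown strand")
    return transcribe(seq) if as_rna else seq
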