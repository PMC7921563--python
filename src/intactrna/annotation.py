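"""Core genomic data types and annotation I/O.

Coordinates are 0-based half-open internally.  GTF I/O converts to and from
the 1-based closed convention of the format.  Transcript "end coordinates"
follow the half-open boundary convention throughout the package: on the plus
strand the 5' end of a transcript is the start of its first exon and the
3' end is the (exclusive) end of its last exon; on the minus strand the two
are swapped.  All strand-aware logic (CAGE/PAS support, end correction,
TSS-polyA clustering) uses these boundary coordinates consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


# An intron chain: ordered (donor, acceptor) boundary pairs in genomic order.
SpliceChain = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-block isoform with strand-aware ends and optional ORF.

    ``cds`` is a (start, end) pair in transcript coordinates (0-based
    half-open along the spliced transcript, 5'->3'), or ``None``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        for e in self.exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValueError("exon chrom/strand must match transcript")
        for a, b in zip(self.exons, self.exons[1:]):
            if not a.end < b.start:
                raise ValueError(
                    f"exons must be sorted, non-overlapping and non-adjacent: "
                    f"{(a.start, a.end)} vs {(b.start, b.end)}"
                )
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= self.length):
                raise ValueError(f"cds {self.cds} outside transcript of length {self.length}")

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def five_prime(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def three_prime(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start


def intron_chain(t: TranscriptModel) -> SpliceChain:
    """The ordered (donor, acceptor) pairs between consecutive exons.

    Empty for single-exon transcripts.  Chain equality (ends unconstrained)
    is the full-length support criterion used throughout the pipeline.
    """
    return tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))


def block_chain(blocks: Sequence[tuple[int, int]]) -> SpliceChain:
    """Intron chain of a plain (start, end) block list (e.g. a read alignment)."""
    return tuple((a[1], b[0]) for a, b in zip(blocks, blocks[1:]))


def transcript_ends(t: TranscriptModel) -> tuple[int, int]:
    """(five_prime, three_prime) boundary coordinates, strand-aware."""
    return t.five_prime, t.three_prime


class Transcriptome:
    """A collection of transcript models with gene and interval indices."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._by_id: dict[str, TranscriptModel] = {}
        self._by_gene: dict[str, set[str]] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_id:
            raise AnnotationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._by_id[t.transcript_id] = t
        self._by_gene.setdefault(t.gene_id, set()).add(t.transcript_id)
        tree = self._trees.setdefault((t.chrom, t.strand), IntervalTree())
        tree.addi(t.span.start, t.span.end, t.transcript_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(sorted(self._by_id.values(), key=lambda t: (t.chrom, t.span.start, t.transcript_id)))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def gene_ids(self) -> set[str]:
        return set(self._by_gene)

    def gene_transcripts(self, gene_id: str) -> set[str]:
        return set(self._by_gene.get(gene_id, set()))

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self._by_id[i] for i in hits]


# ---------------------------------------------------------------------------
# GTF I/O


def _attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_annotation(path: str) -> Transcriptome:
    """Read a GTF file into a :class:`Transcriptome`.

    Only ``exon`` features are required; they must carry ``transcript_id``
    and ``gene_id`` attributes.  ``CDS`` features, when present, are folded
    into transcript-coordinate ORF boundaries.  GTF 1-based closed
    coordinates become 0-based half-open; exon order in the file is
    irrelevant (exons are canonically sorted on load).  Transcripts on
    strand '.' are rejected: end support is strand-aware throughout.
    """
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps sqlite/parse errors
        raise AnnotationError(f"failed to parse GTF {path!r}: {exc}") from exc

    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    cds_genomic: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = _attr(feat, "transcript_id")
        gid = _attr(feat, "gene_id")
        if not tid or not gid:
            log.warning("record without transcript_id/gene_id skipped: %s:%s-%s", feat.seqid, feat.start, feat.end)
            continue
        if feat.strand not in STRANDS:
            raise AnnotationError(f"transcript {tid!r} has unstranded feature (strand {feat.strand!r})")
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(feat)
            meta[tid] = (gid, feat.seqid, feat.strand)
        else:
            cds_genomic.setdefault(tid, []).append((feat.start - 1, feat.end))

    out = Transcriptome()
    for tid, feats in exons.items():
        gid, chrom, strand = meta[tid]
        ivs = tuple(
            sorted(
                (GenomicInterval(chrom, f.start - 1, f.end, strand) for f in feats),
                key=lambda iv: iv.start,
            )
        )
        model = TranscriptModel(tid, gid, chrom, strand, ivs)
        cds = None
        if tid in cds_genomic:
            gs = min(s for s, _ in cds_genomic[tid])
            ge = max(e for _, e in cds_genomic[tid])
            lo = genomic_to_transcript(model, gs, boundary="start")
            hi = genomic_to_transcript(model, ge, boundary="end")
            cds = (min(lo, hi), max(lo, hi))
        out.add(replace(model, cds=cds))
    return out


def write_annotation(transcriptome: Transcriptome, path: str, source: str = "intactrna") -> None:
    """Write a Transcriptome as GTF (transcript + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        for t in transcriptome:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.span.start + 1}\t{t.span.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{attrs}\n")
            if t.cds is not None:
                for gs, ge in cds_genomic_blocks(t):
                    fh.write(f"{t.chrom}\t{source}\tCDS\t{gs + 1}\t{ge}\t.\t{t.strand}\t.\t{attrs}\n")


def write_ends_bed(transcriptome: Transcriptome, path: str) -> None:
    """BED6 export of transcript end positions (name = <tid>:5p / <tid>:3p)."""
    with open(path, "w") as fh:
        for t in transcriptome:
            for tag, pos in zip(("5p", "3p"), transcript_ends(t)):
                fh.write(f"{t.chrom}\t{max(pos - 1, 0)}\t{pos if pos > 0 else 1}\t{t.transcript_id}:{tag}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Coordinate transforms and sequences


def transcript_to_genomic(t: TranscriptModel, pos: int) -> int:
    """Map a transcript coordinate (0-based, 5'->3') to the genomic base position."""
    if not 0 <= pos < t.length:
        raise ValueError(f"position {pos} outside transcript of length {t.length}")
    if t.strand == "+":
        off = pos
        for e in t.exons:
            if off < len(e):
                return e.start + off
            off -= len(e)
    else:
        off = pos
        for e in reversed(t.exons):
            if off < len(e):
                return e.end - 1 - off
            off -= len(e)
    raise AssertionError("unreachable")


def genomic_to_transcript(t: TranscriptModel, coord: int, boundary: str = "start") -> int:
    """Map a genomic boundary coordinate onto the spliced transcript.

    ``coord`` is interpreted as a half-open boundary; ``boundary`` selects
    whether it marks the start ("start") or end ("end") of a genomic block,
    which matters only for deciding which side of a junction it lies on.
    """
    acc = 0
    exon_iter = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    for e in exon_iter:
        if boundary == "start":
            ok = e.start <= coord < e.end
        else:
            ok = e.start < coord <= e.end
        if ok:
            return acc + (coord - e.start if t.strand == "+" else e.end - coord)
        acc += len(e)
    raise ValueError(f"coordinate {coord} not within exons of {t.transcript_id}")


def cds_genomic_blocks(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks covered by the transcript's CDS."""
    if t.cds is None:
        return []
    s, e = t.cds
    positions = sorted(transcript_to_genomic(t, p) for p in (s, e - 1))
    gs, ge = positions[0], positions[1] + 1
    blocks = []
    for ex in t.exons:
        lo, hi = max(ex.start, gs), min(ex.end, ge)
        if lo < hi:
            blocks.append((lo, hi))
    return blocks


def transcript_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on '-')."""
    chrom_seq = genome[t.chrom]
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF finding


def longest_orf(sequence: str, min_length: int = 30) -> Optional[tuple[int, int]]:
    """Longest AUG-initiated ORF ending in a stop codon, any forward frame.

    Returns (start, end) in transcript coordinates with ``end`` just past the
    stop codon, or ``None`` if no ORF of at least ``min_length`` nt (start
    through stop inclusive) exists.  Ties are broken by the 5'-most start.
    """
    seq = sequence.upper()
    best: Optional[tuple[int, int]] = None
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = i + 3 - start
                if length >= min_length:
                    if best is None or length > best[1] - best[0] or (
                        length == best[1] - best[0] and start < best[0]
                    ):
                        best = (start, i + 3)
                start = None
    return best
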