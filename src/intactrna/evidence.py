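"""Read-level CAGE and PAS filtering, internal-priming resolution, peak calling.

CAGE (cap analysis of gene expression) reads carry two template-switching
guanosines at their 5' end: only reads whose second base is G (the "NG or
GG" structure) are genuine capped 5' ends, and those two bases are trimmed
before placement.  PAS (polyadenylation-site) reads begin with a GGG-like
triplet and must end in three or more adenosines; the read is placed on the
genome both with and without its maximal terminal A-run.  If the *tailed*
variant places, the A-run is genome-templated, i.e. the read originated
from oligo-dT priming inside a transcript (internal priming) and is
discarded; otherwise the 3' end of the tailless placement is the cleavage
and polyadenylation site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import reverse_complement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndTag:
    """A single observed transcript end (TSS or cleavage site) with multiplicity.

    ``position`` uses the boundary convention of :mod:`intactrna.annotation`:
    a plus-strand 5' tag sits at the start boundary of the placement, a
    minus-strand 5' tag at its end boundary, and symmetrically for 3' tags.
    """

    chrom: str
    strand: str
    position: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class EndPeak:
    """A positional cluster of end tags with its highest-count position."""

    chrom: str
    strand: str
    start: int
    end: int
    total_count: int
    mode: int

    def __post_init__(self) -> None:
        if not self.start <= self.mode < self.end:
            raise ValueError("require start <= mode < end")

    def supports(self, position: int, window: int = 0) -> bool:
        return self.start - window <= position < self.end + window


@dataclass(frozen=True)
class Placement:
    """An exact, unique, ungapped genomic placement of a short read."""

    chrom: str
    strand: str
    start: int
    end: int

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PasReadCall:
    """Outcome of the PAS read screen + internal-priming resolution."""

    read_id: str
    status: str  # rejected_structure | internal_priming | retained
    cleavage_site: Optional[EndTag] = None
    trailing_a_count: int = 0

    def __post_init__(self) -> None:
        if (self.status == "retained") != (self.cleavage_site is not None):
            raise ValueError("cleavage_site present iff status == 'retained'")


def filter_cage_read(read_sequence: str, min_length: int = 3) -> Optional[str]:
    """Retain a CAGE read iff it begins with NG or GG; trim the first 2 nt.

    Returns the trimmed sequence or ``None``.  Reads shorter than
    ``min_length`` (default 3 nt) are rejected outright.
    """
    seq = read_sequence.upper()
    if len(seq) < min_length or len(seq) < 3:
        return None
    if seq[1] != "G":
        return None
    return seq[2:]


_PAS_PREFIXES = ("GGG", "NGG", "NNG", "GNG")


def _matches_pas_prefix(head: str) -> bool:
    for pat in _PAS_PREFIXES:
        if all(p == "N" or p == b for p, b in zip(pat, head)):
            return True
    return False


def screen_pas_read(
    read_sequence: str, min_trailing_a: int = 3, min_body: int = 1
) -> Optional[tuple[str, str, int]]:
    """Structural screen of a PAS read.

    Retained iff the first three bases match one of GGG/NGG/NNG/GNG (N = any
    base) and the read ends with at least ``min_trailing_a`` adenosines.
    Returns ``(tailless, tailed, trailing_a_count)`` where ``tailed`` is the
    read minus its 3-nt prefix and ``tailless`` additionally lacks the
    maximal terminal A-run; internal A's are untouched.
    """
    seq = read_sequence.upper()
    if len(seq) < 3 or not _matches_pas_prefix(seq[:3]):
        return None
    body = seq[3:]
    n_a = len(body) - len(body.rstrip("A"))
    if n_a < min_trailing_a:
        return None
    tailless = body[: len(body) - n_a]
    if len(tailless) < min_body:
        return None
    return tailless, body, n_a


def resolve_internal_priming(
    read_id: str,
    tailless_alignment: Optional[Placement],
    tailed_alignment: Optional[Placement],
    trailing_a_count: int = 0,
) -> PasReadCall:
    """Classify a screened PAS read from its two placement attempts.

    Any placement of the tailed variant means the trailing adenosines are
    genome-templated: internal priming, discarded.  Otherwise a placing
    tailless variant is retained and its strand-aware 3' end reported as the
    cleavage/polyadenylation site.
    """
    if (
        tailless_alignment is not None
        and tailed_alignment is not None
        and (
            tailless_alignment.chrom != tailed_alignment.chrom
            or tailless_alignment.strand != tailed_alignment.strand
        )
    ):
        raise ValueError(f"inconsistent placements for read {read_id!r}")
    if tailed_alignment is not None:
        return PasReadCall(read_id, "internal_priming", None, trailing_a_count)
    if tailless_alignment is not None:
        site = EndTag(
            tailless_alignment.chrom,
            tailless_alignment.strand,
            tailless_alignment.three_prime(),
        )
        return PasReadCall(read_id, "retained", site, trailing_a_count)
    return PasReadCall(read_id, "rejected_structure", None, trailing_a_count)


def exact_place(sequence: str, genome: Mapping[str, str]) -> Optional[Placement]:
    """Unique exact occurrence of ``sequence`` in the genome, either strand.

    Suitable for the toy genomes this package simulates; multiple
    occurrences are ambiguous and return ``None``.
    """
    seq = sequence.upper()
    if not seq:
        return None
    rc = reverse_complement(seq)
    hits: list[Placement] = []
    for chrom in sorted(genome):
        ref = genome[chrom]
        for probe, strand in ((seq, "+"), (rc, "-")):
            start = ref.find(probe)
            while start != -1:
                hits.append(Placement(chrom, strand, start, start + len(probe)))
                if len(hits) > 1:
                    log.debug("ambiguous placement for %s...", seq[:12])
                    return None
                start = ref.find(probe, start + 1)
    if len(hits) != 1:
        return None
    return hits[0]


def call_end_peaks(
    tags: Iterable[EndTag], max_gap: int = 20, min_count: int = 2
) -> list[EndPeak]:
    """Single-linkage run clustering of end tags into peaks.

    Tag positions on the same chrom/strand whose consecutive sorted
    positions differ by at most ``max_gap`` form one candidate peak;
    candidates whose total tag count is below ``min_count`` are dropped.
    The peak mode is the highest-count position, ties broken by the 5'-most
    position on the tag's strand.
    """
    by_key: dict[tuple[str, str], dict[int, int]] = {}
    for t in tags:
        counts = by_key.setdefault((t.chrom, t.strand), {})
        counts[t.position] = counts.get(t.position, 0) + t.count

    peaks: list[EndPeak] = []
    for (chrom, strand), counts in sorted(by_key.items()):
        positions = sorted(counts)
        run: list[int] = []
        for pos in positions + [None]:  # type: ignore[list-item]
            if run and (pos is None or pos - run[-1] > max_gap):
                total = sum(counts[p] for p in run)
                if total >= min_count:
                    best = max(counts[p] for p in run)
                    candidates = [p for p in run if counts[p] == best]
                    mode = min(candidates) if strand == "+" else max(candidates)
                    peaks.append(EndPeak(chrom, strand, run[0], run[-1] + 1, total, mode))
                run = []
            if pos is not None:
                run.append(pos)
    return peaks


# ---------------------------------------------------------------------------
# Library-level wrappers: FASTQ in, tags/calls out


def process_cage_reads(
    reads: Iterable[tuple[str, str]],
    genome: Mapping[str, str],
    min_trimmed_length: int = 18,
) -> list[EndTag]:
    """Run the CAGE read filter and exact placement over (id, sequence) pairs.

    The strand-aware 5' end of each uniquely placed, retained read becomes a
    transcription start site tag.  Reads shorter than ``min_trimmed_length``
    after trimming are dropped (too short to place reliably).
    """
    tags: list[EndTag] = []
    for _rid, seq in reads:
        trimmed = filter_cage_read(seq)
        if trimmed is None or len(trimmed) < min_trimmed_length:
            continue
        placement = exact_place(trimmed, genome)
        if placement is None:
            continue
        tags.append(EndTag(placement.chrom, placement.strand, placement.five_prime()))
    return tags


def process_pas_reads(
    reads: Iterable[tuple[str, str]],
    genome: Mapping[str, str],
    min_trailing_a: int = 3,
    min_body: int = 18,
) -> tuple[list[EndTag], list[PasReadCall]]:
    """Screen, place and classify PAS reads; return retained cleavage-site tags
    plus the full per-read call table."""
    sites: list[EndTag] = []
    calls: list[PasReadCall] = []
    for rid, seq in reads:
        screened = screen_pas_read(seq, min_trailing_a=min_trailing_a, min_body=min_body)
        if screened is None:
            calls.append(PasReadCall(rid, "rejected_structure"))
            continue
        tailless, tailed, n_a = screened
        call = resolve_internal_priming(
            rid, exact_place(tailless, genome), exact_place(tailed, genome), n_a
        )
        calls.append(call)
        if call.status == "retained":
            assert call.cleavage_site is not None
            sites.append(call.cleavage_site)
    return sites, calls


def read_fastq(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


def write_tags_bed(tags: Sequence[EndTag], path: str) -> None:
    """BED6: one 1-nt record per site (start = boundary coordinate), score = count."""
    with open(path, "w") as fh:
        for t in sorted(tags, key=lambda t: (t.chrom, t.position, t.strand)):
            fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\tend_tag\t{t.count}\t{t.strand}\n")


def write_peaks_bed(peaks: Sequence[EndPeak], path: str) -> None:
    """BED6+1: score = total_count, column 7 = mode."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.strand)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.total_count}\t{p.strand}\t{p.mode}\n")


def read_peaks_bed(path: str) -> list[EndPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score, strand, mode = line.rstrip("\n").split("\t")[:7]
            peaks.append(EndPeak(chrom, strand, int(start), int(end), int(score), int(mode)))
    return peaks


def read_tags_bed(path: str) -> list[EndTag]:
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            tags.append(EndTag(chrom, strand, int(start), int(score)))
    return tags
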