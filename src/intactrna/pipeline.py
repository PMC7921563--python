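"""The intact-transcript identification pipeline.

Long reads from single-molecule sequencing cannot by themselves distinguish
an intact, capped and polyadenylated transcript from a 5'-truncated decay
intermediate or an internally primed artifact.  The pipeline therefore
combines three lines of evidence:

1. splice-pattern support — a read is full-length for an isoform iff its
   intron chain equals the isoform's chain (end coordinates unconstrained);
2. 5'-cap evidence — the read's genomic 5' end falls in a CAGE peak, or
   near an annotated reference TSS;
3. polyadenylation evidence — the read's genomic 3' end falls near a
   cleavage site called from internal-priming-filtered PAS reads, or near
   an annotated reference 3' end.

A read with both end supports is an intact long read.  Isoforms with at
least one intact full-length read are emitted, their terminal exon
boundaries corrected to the supporting CAGE peak mode / PAS cleavage site.
Reads matching no annotated or assembled splice pattern can still be
rescued as novel isoforms when at least ``min_cluster_size`` reads share an
identical intron chain with CAGE support at the 5' end and PAS support at
the 3' end.  Finally, the (CAGE peak, read 3' end) coordinate pairs of each
isoform's full-length reads are clustered into TSS-polyA isoforms.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import (
    GenomicInterval,
    SpliceChain,
    TranscriptModel,
    Transcriptome,
    block_chain,
    intron_chain,
)
from .evidence import EndPeak, EndTag

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


class CorrectionError(ValueError):
    """End correction would invert a terminal exon."""


@dataclass(frozen=True)
class AlignedLongRead:
    """A spliced long-read alignment: ordered blocks plus end-clip lengths.

    ``clip5``/``clip3`` are the soft/hard-clipped lengths at the *read's*
    5' and 3' ends (strand-aware, i.e. clip5 is the clip at the leftmost
    alignment column for '+' reads and the rightmost for '-' reads).
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    clip5: int = 0
    clip3: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read needs at least one alignment block")
        if self.clip5 < 0 or self.clip3 < 0:
            raise ValueError("clip lengths must be >= 0")
        for (s, e) in self.blocks:
            if not s < e:
                raise ValueError(f"bad block ({s}, {e})")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not a[1] < b[0]:
                raise ValueError("blocks must be sorted and non-overlapping")

    @property
    def chain(self) -> SpliceChain:
        return block_chain(self.blocks)

    @property
    def five_end(self) -> int:
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1]

    @property
    def three_end(self) -> int:
        return self.blocks[-1][1] if self.strand == "+" else self.blocks[0][0]

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class SupportCall:
    """Which annotated/assembled isoforms a read is full-length for."""

    read_id: str
    matched_transcript_ids: frozenset[str]
    support_source: str  # refseq | sr_assembly | none

    def __post_init__(self) -> None:
        if (self.support_source == "none") != (not self.matched_transcript_ids):
            raise ValueError("support_source == 'none' iff matched set empty")


@dataclass(frozen=True)
class EndSupport:
    """Per-read end support: basis and the concrete evidence object."""

    five_basis: Optional[str]  # cage | refseq | None
    three_basis: Optional[str]  # pas | refseq | None
    cage_peak: Optional[EndPeak] = None
    pas_site: Optional[EndTag] = None

    @property
    def intact(self) -> bool:
        return self.five_basis is not None and self.three_basis is not None


@dataclass
class IntactIsoform:
    """A transcript emitted as intact, with its end-support provenance."""

    model: TranscriptModel
    source: str  # refseq_match | sr_assembly_match | novel_rescued
    five_prime_basis: str  # cage | refseq
    three_prime_basis: str  # pas | refseq
    supporting_read_ids: tuple[str, ...] = ()
    cage_peak: Optional[EndPeak] = None
    pas_evidence: Optional[EndTag] = None
    correction_flagged: bool = False

    def __post_init__(self) -> None:
        if self.five_prime_basis not in ("cage", "refseq"):
            raise ValueError(f"bad five_prime_basis {self.five_prime_basis!r}")
        if self.three_prime_basis not in ("pas", "refseq"):
            raise ValueError(f"bad three_prime_basis {self.three_prime_basis!r}")
        if self.source == "novel_rescued":
            if self.five_prime_basis != "cage" or self.three_prime_basis != "pas":
                raise ValueError("novel isoforms require cage and pas end bases")
            if len(self.supporting_read_ids) < 2:
                raise ValueError("novel isoforms require >= 2 supporting reads")


@dataclass(frozen=True)
class TssPolyaIsoform:
    """A (TSS, polyA) refinement of a base isoform with its read count."""

    base_isoform_id: str
    tss: int
    polya: int
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class PipelineConfig:
    """Tunables of the assembly; defaults follow the pipeline description."""

    max_clip: int = 100
    junction_tolerance: int = 0
    support_window: int = 50
    min_cluster_size: int = 2
    linkage_distance: int = 100
    refseq_only: bool = False  # allow running without CAGE/PAS tracks
    prefer_evidence: bool = True  # cage/pas basis wins over refseq when both hold


@dataclass
class AssemblyResult:
    transcriptome: Transcriptome
    isoforms: list[IntactIsoform]
    tss_polya: list[TssPolyaIsoform]
    step_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Step primitives


def filter_by_clipping(
    reads: Iterable[AlignedLongRead], max_clip: int = 100
) -> list[AlignedLongRead]:
    """Drop reads with clipping regions *longer than* ``max_clip`` nt at
    either end (boundary inclusive: a 100-nt clip is retained at default)."""
    return [r for r in reads if r.clip5 <= max_clip and r.clip3 <= max_clip]


def _chains_equal(a: SpliceChain, b: SpliceChain, tol: int) -> bool:
    if len(a) != len(b):
        return False
    if tol == 0:
        return a == b
    return all(
        abs(x1 - y1) <= tol and abs(x2 - y2) <= tol for (x1, x2), (y1, y2) in zip(a, b)
    )


def match_splice_pattern(
    read: AlignedLongRead,
    annotations: Transcriptome,
    junction_tolerance: int = 0,
    source: str = "refseq",
) -> SupportCall:
    """Full-length support: the read's intron chain equals a transcript's
    chain within the junction tolerance; ends are never constrained.

    A junction-free (single-exon) read matches a single-exon transcript iff
    the read's block lies within that transcript's exon.  Sub-chains do not
    count as support: a truncated read that lost a junction matches nothing.
    """
    s, e = read.span
    matched = set()
    read_chain = read.chain
    for t in annotations.overlapping(read.chrom, read.strand, s, e):
        t_chain = intron_chain(t)
        if read_chain:
            if _chains_equal(read_chain, t_chain, junction_tolerance):
                matched.add(t.transcript_id)
        else:
            if not t_chain and t.exons[0].start <= s and e <= t.exons[0].end:
                matched.add(t.transcript_id)
    if not matched:
        return SupportCall(read.read_id, frozenset(), "none")
    return SupportCall(read.read_id, frozenset(matched), source)


def end_support(
    read: AlignedLongRead,
    cage_peaks: Sequence[EndPeak],
    pas_sites: Sequence[EndTag],
    annotations: Optional[Transcriptome],
    window: int = 50,
) -> EndSupport:
    """Classify the read's two genomic ends against the evidence tracks.

    5' basis: 'cage' if the read's 5' end lies within a same-strand CAGE
    peak extended by ``window`` (nearest mode wins), else 'refseq' if within
    ``window`` of an annotated TSS, else absent.  3' basis symmetric with
    PAS cleavage sites / annotated 3' ends.  Opposite-strand evidence never
    supports.
    """
    five = read.five_end
    three = read.three_end

    best_peak: Optional[EndPeak] = None
    for p in cage_peaks:
        if p.chrom == read.chrom and p.strand == read.strand and p.supports(five, window):
            if best_peak is None or abs(p.mode - five) < abs(best_peak.mode - five):
                best_peak = p
    five_basis = "cage" if best_peak is not None else None

    best_site: Optional[EndTag] = None
    for t in pas_sites:
        if t.chrom == read.chrom and t.strand == read.strand and abs(t.position - three) <= window:
            if best_site is None or abs(t.position - three) < abs(best_site.position - three):
                best_site = t
    three_basis = "pas" if best_site is not None else None

    if annotations is not None and (five_basis is None or three_basis is None):
        lo = min(five, three) - window
        hi = max(five, three) + window + 1
        for t in annotations.overlapping(read.chrom, read.strand, lo, hi):
            if five_basis is None and abs(t.five_prime - five) <= window:
                five_basis = "refseq"
            if three_basis is None and abs(t.three_prime - three) <= window:
                three_basis = "refseq"
    return EndSupport(five_basis, three_basis, best_peak, best_site)


def correct_ends(
    isoform_model: TranscriptModel,
    cage_mode: Optional[int] = None,
    pas_position: Optional[int] = None,
) -> TranscriptModel:
    """Move terminal exon boundaries to the CAGE peak mode / PAS site.

    Internal junctions are untouched.  Raises :class:`CorrectionError` when
    the corrected boundary would cross the terminal exon's junction (an
    inverted exon).
    """
    exons = list(isoform_model.exons)
    strand = isoform_model.strand
    chrom = isoform_model.chrom

    def set_start(i: int, new_start: int) -> None:
        if not new_start < exons[i].end:
            raise CorrectionError(
                f"corrected start {new_start} inverts exon {(exons[i].start, exons[i].end)}"
            )
        exons[i] = GenomicInterval(chrom, new_start, exons[i].end, strand)

    def set_end(i: int, new_end: int) -> None:
        if not exons[i].start < new_end:
            raise CorrectionError(
                f"corrected end {new_end} inverts exon {(exons[i].start, exons[i].end)}"
            )
        exons[i] = GenomicInterval(chrom, exons[i].start, new_end, strand)

    if cage_mode is not None:
        if strand == "+":
            if len(exons) > 1 and cage_mode >= exons[0].end:
                raise CorrectionError("CAGE mode beyond the first junction")
            set_start(0, cage_mode)
        else:
            if len(exons) > 1 and cage_mode <= exons[-1].start:
                raise CorrectionError("CAGE mode beyond the first junction")
            set_end(len(exons) - 1, cage_mode)
    if pas_position is not None:
        if strand == "+":
            if len(exons) > 1 and pas_position <= exons[-1].start:
                raise CorrectionError("PAS site beyond the last junction")
            set_end(len(exons) - 1, pas_position)
        else:
            if len(exons) > 1 and pas_position >= exons[0].end:
                raise CorrectionError("PAS site beyond the last junction")
            set_start(0, pas_position)
    return replace(isoform_model, exons=tuple(exons), cds=None)


def _group_reads_by_chain(
    reads: Sequence[AlignedLongRead], tol: int
) -> list[list[AlignedLongRead]]:
    """Group same-chrom/strand reads with equal intron chains (within tol)."""
    buckets: dict[tuple[str, str, int], list[AlignedLongRead]] = defaultdict(list)
    for r in reads:
        buckets[(r.chrom, r.strand, len(r.chain))].append(r)
    groups: list[list[AlignedLongRead]] = []
    for key, rs in sorted(buckets.items()):
        if key[2] == 0:
            # junction-free reads carry no chain; the caller decides how to
            # partition them (rescue groups them by shared end evidence)
            groups.extend([[r] for r in rs])
            continue
        if tol == 0:
            by_chain: dict[SpliceChain, list[AlignedLongRead]] = defaultdict(list)
            for r in rs:
                by_chain[r.chain].append(r)
            groups.extend(by_chain[c] for c in sorted(by_chain))
        else:
            parent = list(range(len(rs)))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(rs)):
                for j in range(i + 1, len(rs)):
                    if _chains_equal(rs[i].chain, rs[j].chain, tol):
                        parent[find(i)] = find(j)
            comp: dict[int, list[AlignedLongRead]] = defaultdict(list)
            for i, r in enumerate(rs):
                comp[find(i)].append(r)
            groups.extend(comp[k] for k in sorted(comp))
    return groups


def _modal(values: Iterable[int]) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def rescue_novel(
    unmatched_reads: Sequence[AlignedLongRead],
    cage_peaks: Sequence[EndPeak],
    pas_sites: Sequence[EndTag],
    min_cluster_size: int = 2,
    window: int = 50,
    junction_tolerance: int = 0,
    id_prefix: str = "novel",
) -> list[IntactIsoform]:
    """Recover novel isoforms from reads with no splice-pattern support.

    CAGE-supported reads are grouped by identical intron chain; groups of at
    least ``min_cluster_size`` reads with at least one PAS-supported 3' end
    become novel isoforms.  Exons: junctions are the per-junction modal
    coordinates of the group, terminal boundaries come from end correction
    (CAGE mode, PAS site).  Junction-free reads, which carry no chain, are
    grouped by their shared (CAGE peak, PAS site) evidence pair instead.
    """
    supported: list[tuple[AlignedLongRead, EndSupport]] = []
    for r in unmatched_reads:
        sup = end_support(r, cage_peaks, pas_sites, None, window)
        if sup.five_basis == "cage":
            supported.append((r, sup))

    sup_by_id = {r.read_id: s for r, s in supported}
    multi = [r for r, _ in supported if r.chain]
    single = [(r, s) for r, s in supported if not r.chain]

    groups: list[list[AlignedLongRead]] = [
        g for g in _group_reads_by_chain(multi, junction_tolerance) if len(g[0].chain) > 0
    ]
    single_groups: dict[tuple, list[AlignedLongRead]] = defaultdict(list)
    for r, s in single:
        assert s.cage_peak is not None
        pas_pos = s.pas_site.position if s.pas_site is not None else None
        single_groups[(r.chrom, r.strand, s.cage_peak.mode, pas_pos)].append(r)
    groups.extend(single_groups[k] for k in sorted(single_groups, key=str))

    isoforms: list[IntactIsoform] = []
    n = 0
    for group in groups:
        if len(group) < min_cluster_size:
            continue
        pas_supported = [r for r in group if sup_by_id[r.read_id].pas_site is not None]
        if not pas_supported:
            continue
        n += 1
        chrom, strand = group[0].chrom, group[0].strand
        n_junc = len(group[0].chain)
        junctions = tuple(
            (
                _modal(r.chain[j][0] for r in group),
                _modal(r.chain[j][1] for r in group),
            )
            for j in range(n_junc)
        )
        cage_peak = sup_by_id[group[0].read_id].cage_peak
        assert cage_peak is not None
        pas_site = sup_by_id[pas_supported[0].read_id].pas_site
        assert pas_site is not None

        # provisional terminal boundaries from the widest supporting read
        left = min(r.blocks[0][0] for r in group)
        right = max(r.blocks[-1][1] for r in group)
        bounds = [left] + [c for j in junctions for c in j] + [right]
        exons = tuple(
            GenomicInterval(chrom, bounds[i], bounds[i + 1], strand)
            for i in range(0, len(bounds), 2)
        )
        model = TranscriptModel(f"{id_prefix}_{n}", f"{id_prefix}_gene_{n}", chrom, strand, exons)
        flagged = False
        try:
            model = correct_ends(model, cage_peak.mode, pas_site.position)
        except CorrectionError:
            flagged = True
        isoforms.append(
            IntactIsoform(
                model=model,
                source="novel_rescued",
                five_prime_basis="cage",
                three_prime_basis="pas",
                supporting_read_ids=tuple(sorted(r.read_id for r in group)),
                cage_peak=cage_peak,
                pas_evidence=pas_site,
                correction_flagged=flagged,
            )
        )
    return isoforms


def cluster_tss_polya(
    pairs_per_isoform: Mapping[str, Sequence[tuple[int, int]]],
    linkage_distance: int = 100,
) -> list[TssPolyaIsoform]:
    """Single-linkage clustering of (CAGE peak mode, read 3' end) pairs under
    Chebyshev distance, one TSS-polyA isoform per cluster.

    TSS/polyA of a cluster are the modal coordinates; read_count its size.
    """
    out: list[TssPolyaIsoform] = []
    for iso_id in sorted(pairs_per_isoform):
        pairs = list(pairs_per_isoform[iso_id])
        if not pairs:
            continue
        parent = list(range(len(pairs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                if (
                    max(abs(pairs[i][0] - pairs[j][0]), abs(pairs[i][1] - pairs[j][1]))
                    <= linkage_distance
                ):
                    parent[find(i)] = find(j)
        comp: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for i, p in enumerate(pairs):
            comp[find(i)].append(p)
        for k in sorted(comp, key=lambda k: (min(comp[k]), k)):
            members = comp[k]
            out.append(
                TssPolyaIsoform(
                    iso_id,
                    tss=_modal(p[0] for p in members),
                    polya=_modal(p[1] for p in members),
                    read_count=len(members),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Full assembly


def assemble_final(
    annotations: Transcriptome,
    sr_assembly: Optional[Transcriptome],
    long_reads: Sequence[AlignedLongRead],
    cage_peaks: Optional[Sequence[EndPeak]],
    pas_sites: Optional[Sequence[EndTag]],
    config: Optional[PipelineConfig] = None,
) -> AssemblyResult:
    """Run the full pipeline: clip filter -> splice-pattern match (reference,
    then short-read assembly) -> end support and correction -> novel rescue
    -> TSS-polyA clustering.

    PAS sites passed in must already have internal-priming reads removed
    (see :mod:`intactrna.evidence`).  Without both evidence tracks the
    pipeline refuses to emit calls unless ``config.refseq_only`` is set.
    """
    cfg = config or PipelineConfig()
    if (cage_peaks is None or pas_sites is None) and not cfg.refseq_only:
        raise PipelineError(
            "CAGE/PAS evidence track missing; set refseq_only=True to emit "
            "reference-end-based calls only"
        )
    cage_peaks = list(cage_peaks or [])
    pas_sites = list(pas_sites or [])

    counts: dict[str, int] = {"input_reads": len(long_reads)}
    reads = filter_by_clipping(long_reads, cfg.max_clip)
    counts["clip_filtered"] = len(reads)

    # step i-ii: full-length splice-pattern support, reference first
    support: dict[str, SupportCall] = {}
    ends: dict[str, EndSupport] = {}
    reads_by_id = {r.read_id: r for r in reads}
    per_transcript: dict[str, list[str]] = defaultdict(list)
    unmatched: list[AlignedLongRead] = []
    for r in reads:
        # matches against the reference and the short-read assembly are both
        # recorded; the reference is credited as the support source when it
        # matches (identical chains can live in both annotation sets)
        ref_call = match_splice_pattern(r, annotations, cfg.junction_tolerance, "refseq")
        sr_call = (
            match_splice_pattern(r, sr_assembly, cfg.junction_tolerance, "sr_assembly")
            if sr_assembly is not None
            else SupportCall(r.read_id, frozenset(), "none")
        )
        matched_ids = ref_call.matched_transcript_ids | sr_call.matched_transcript_ids
        source = (
            "refseq"
            if ref_call.matched_transcript_ids
            else ("sr_assembly" if sr_call.matched_transcript_ids else "none")
        )
        call = SupportCall(r.read_id, frozenset(matched_ids), source)
        support[r.read_id] = call
        ends[r.read_id] = end_support(r, cage_peaks, pas_sites, annotations, cfg.support_window)
        if call.support_source == "none":
            unmatched.append(r)
        else:
            for tid in call.matched_transcript_ids:
                per_transcript[tid].append(r.read_id)
    counts["matched_reads"] = len(reads) - len(unmatched)
    counts["unmatched_reads"] = len(unmatched)

    # step iii: intactness call + end correction per matched transcript
    isoforms: list[IntactIsoform] = []
    for tid in sorted(per_transcript):
        src_tome = annotations if tid in annotations else sr_assembly
        assert src_tome is not None
        model = src_tome[tid]
        rids = per_transcript[tid]
        intact_rids = [rid for rid in rids if ends[rid].intact]
        if not intact_rids:
            continue

        cage_cands = [ends[rid].cage_peak for rid in intact_rids if ends[rid].cage_peak is not None]
        pas_cands = [ends[rid].pas_site for rid in intact_rids if ends[rid].pas_site is not None]
        has_ref5 = any(ends[rid].five_basis == "refseq" for rid in intact_rids)
        has_ref3 = any(ends[rid].three_basis == "refseq" for rid in intact_rids)

        peak = min(cage_cands, key=lambda p: (abs(p.mode - model.five_prime), p.mode), default=None)
        site = min(
            pas_cands, key=lambda s: (abs(s.position - model.three_prime), s.position), default=None
        )
        if cfg.prefer_evidence:
            five_basis = "cage" if peak is not None else ("refseq" if has_ref5 else None)
            three_basis = "pas" if site is not None else ("refseq" if has_ref3 else None)
        else:
            five_basis = "refseq" if has_ref5 else ("cage" if peak is not None else None)
            three_basis = "refseq" if has_ref3 else ("pas" if site is not None else None)
        if five_basis is None or three_basis is None:
            continue

        flagged = False
        corrected = model
        try:
            corrected = correct_ends(
                model,
                peak.mode if five_basis == "cage" and peak is not None else None,
                site.position if three_basis == "pas" and site is not None else None,
            )
        except CorrectionError:
            flagged = True
        isoforms.append(
            IntactIsoform(
                model=replace(corrected, transcript_id=tid, gene_id=model.gene_id),
                source="refseq_match" if tid in annotations else "sr_assembly_match",
                five_prime_basis=five_basis,
                three_prime_basis=three_basis,
                supporting_read_ids=tuple(sorted(rids)),
                cage_peak=peak if five_basis == "cage" else None,
                pas_evidence=site if three_basis == "pas" else None,
                correction_flagged=flagged,
            )
        )
    counts["matched_isoforms"] = len(isoforms)

    # step iv: novel rescue
    if not cfg.refseq_only:
        novel = rescue_novel(
            unmatched,
            cage_peaks,
            pas_sites,
            min_cluster_size=cfg.min_cluster_size,
            window=cfg.support_window,
            junction_tolerance=cfg.junction_tolerance,
        )
    else:
        novel = []
    counts["novel_isoforms"] = len(novel)
    isoforms.extend(novel)

    # step v: deduplicate identical models into the final assembly
    _SRC_RANK = {"refseq_match": 0, "sr_assembly_match": 1, "novel_rescued": 2}
    merged: dict[tuple, IntactIsoform] = {}
    for iso in isoforms:
        key = (
            iso.model.chrom,
            iso.model.strand,
            intron_chain(iso.model),
            iso.model.five_prime,
            iso.model.three_prime,
        )
        prev = merged.get(key)
        if prev is None:
            merged[key] = iso
        else:
            keep, drop = (
                (prev, iso) if _SRC_RANK[prev.source] <= _SRC_RANK[iso.source] else (iso, prev)
            )
            keep.supporting_read_ids = tuple(
                sorted(set(keep.supporting_read_ids) | set(drop.supporting_read_ids))
            )
            merged[key] = keep
    final = [merged[k] for k in sorted(merged)]
    counts["final_isoforms"] = len(final)

    tome = Transcriptome()
    for iso in final:
        tome.add(
            replace(iso.model, gene_id=iso.model.gene_id, transcript_id=iso.model.transcript_id)
        )

    # TSS-polyA refinement over CAGE-supported full-length reads
    pairs: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iso in final:
        for rid in iso.supporting_read_ids:
            if rid not in reads_by_id:
                continue
            sup = ends.get(rid)
            if sup is None or sup.cage_peak is None:
                continue
            pairs[iso.model.transcript_id].append((sup.cage_peak.mode, reads_by_id[rid].three_end))
    tss_polya = cluster_tss_polya(pairs, cfg.linkage_distance)
    counts["tss_polya_isoforms"] = len(tss_polya)

    for step, value in counts.items():
        log.info("pipeline: %s = %d", step, value)
    return AssemblyResult(tome, final, tss_polya, counts)


def ont_validate(
    isoforms: Transcriptome,
    ont_reads: Iterable[AlignedLongRead],
    junction_tolerance: int = 0,
) -> dict[str, int]:
    """Per-isoform count of full-length validating reads.

    A read validates an isoform iff it covers the same exon set with
    consistent splice sites (chain equality); no 5'/3' end requirement.
    """
    counts = {t.transcript_id: 0 for t in isoforms}
    for r in ont_reads:
        call = match_splice_pattern(r, isoforms, junction_tolerance, "refseq")
        for tid in call.matched_transcript_ids:
            counts[tid] += 1
    return counts


# ---------------------------------------------------------------------------
# SAM / table I/O


def read_sam(path: str) -> list[AlignedLongRead]:
    """Load spliced long-read alignments from SAM/BAM via pysam.

    Blocks merge CIGAR matches across insertions/deletions (splits occur at
    N skips only); clip lengths are strand-aware (clip5 is the leading clip
    for '+' reads, the trailing clip for '-' reads).
    """
    import pysam

    reads: list[AlignedLongRead] = []
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            blocks: list[list[int]] = []
            pos = aln.reference_start
            for op, length in aln.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1][1] = pos + length
                    else:
                        blocks.append([pos, pos + length])
                    pos += length
                elif op == 2:  # D: consumes reference, same block
                    if blocks:
                        blocks[-1][1] = pos + length
                    pos += length
                elif op == 3:  # N: splice
                    pos += length
            cig = aln.cigartuples
            left = cig[0][1] if cig[0][0] in (4, 5) else 0
            right = cig[-1][1] if cig[-1][0] in (4, 5) else 0
            strand = "-" if aln.is_reverse else "+"
            clip5, clip3 = (left, right) if strand == "+" else (right, left)
            reads.append(
                AlignedLongRead(
                    aln.query_name,
                    aln.reference_name,
                    strand,
                    tuple((s, e) for s, e in blocks),
                    clip5,
                    clip3,
                )
            )
    return reads


def write_sam(
    reads: Sequence[AlignedLongRead],
    genome: Mapping[str, str],
    path: str,
    clip_base: str = "T",
) -> None:
    """Write reads as text SAM; clips become soft clips of ``clip_base``."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(genome[name])} for name in sorted(genome)],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            left, right = (r.clip5, r.clip3) if r.strand == "+" else (r.clip3, r.clip5)
            cigar: list[tuple[int, int]] = []
            if left:
                cigar.append((4, left))
            seq_parts = [clip_base * left]
            for i, (s, e) in enumerate(r.blocks):
                if i:
                    cigar.append((3, s - r.blocks[i - 1][1]))
                cigar.append((0, e - s))
                seq_parts.append(genome[r.chrom][s:e])
            if right:
                cigar.append((4, right))
            seq_parts.append(clip_base * right)
            a.cigartuples = cigar
            a.query_sequence = "".join(seq_parts)
            fh.write(a)


def write_intactness_table(isoforms: Sequence[IntactIsoform], path: str) -> None:
    """TSV: isoform_id, source, end bases, read count, evidence ids."""
    with open(path, "w") as fh:
        fh.write(
            "isoform_id\tsource\tfive_prime_basis\tthree_prime_basis\tn_reads\t"
            "cage_peak_mode\tpas_site\tflagged\n"
        )
        for iso in isoforms:
            fh.write(
                "\t".join(
                    [
                        iso.model.transcript_id,
                        iso.source,
                        iso.five_prime_basis,
                        iso.three_prime_basis,
                        str(len(iso.supporting_read_ids)),
                        str(iso.cage_peak.mode) if iso.cage_peak else ".",
                        str(iso.pas_evidence.position) if iso.pas_evidence else ".",
                        "1" if iso.correction_flagged else "0",
                    ]
                )
                + "\n"
            )


def write_tss_polya_bed(
    tss_polya: Sequence[TssPolyaIsoform],
    transcriptome: Transcriptome,
    path: str,
) -> None:
    """BED12 of TSS-polyA isoforms, block structure from the base isoform."""
    with open(path, "w") as fh:
        for i, tp in enumerate(tss_polya):
            t = transcriptome[tp.base_isoform_id]
            lo = min(tp.tss, tp.polya)
            hi = max(tp.tss, tp.polya)
            blocks = [(max(e.start, lo), min(e.end, hi)) for e in t.exons]
            blocks = [(s, e) for s, e in blocks if s < e] or [(lo, hi)]
            starts = ",".join(str(s - lo) for s, _ in blocks) + ","
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            fh.write(
                f"{t.chrom}\t{lo}\t{hi}\t{tp.base_isoform_id}.tp{i + 1}\t{tp.read_count}\t"
                f"{t.strand}\t{lo}\t{hi}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )
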