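"""Ground-truth simulator for every input the pipeline consumes.

The generator emulates the data regime the pipeline was designed for: a toy
genome carrying multi-isoform genes (alternative TSS, exon skipping,
alternative polyadenylation), long reads that are either intact copies of
an isoform or 5'-truncated decay intermediates, alignment end-clips, CAGE
reads with the NG/GG cap signature and optional TSS jitter, PAS reads with
genuine non-templated polyA tails plus internally primed reads seeded by
genomic A-runs, and ribosome footprints with a controlled in-frame
fraction.  Every emitted record carries a ground-truth label, which the
test suite uses as its oracle.

All randomness flows from a single mandatory seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotation import (
    GenomicInterval,
    TranscriptModel,
    Transcriptome,
    intron_chain,
    longest_orf,
    transcript_sequence,
    transcript_to_genomic,
)
from .pipeline import AlignedLongRead, AssemblyResult
from .ribosome import RpfPlacement

log = logging.getLogger(__name__)

CHROM = "chr1"
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the simulation.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 20
    min_isoforms_per_gene: int = 1
    max_isoforms_per_gene: int = 4
    # probabilities that an additional isoform differs by alternative TSS,
    # exon skipping, or alternative polyadenylation (APA dominates, as in
    # tissue-specific transcriptomes)
    p_alt_tss: float = 0.2
    p_alt_splice: float = 0.3
    p_apa: float = 0.5
    novel_gene_fraction: float = 0.25  # genes withheld from the annotated GTF
    sr_only_fraction: float = 0.4  # non-primary annotated isoforms only in SR assembly
    exons_per_gene: tuple[int, int] = (3, 5)
    internal_exon_length: tuple[int, int] = (120, 300)
    terminal_exon_length: tuple[int, int] = (350, 550)
    intron_length: tuple[int, int] = (150, 500)
    intergenic_gap: int = 600  # >= 500 so short probes place uniquely

    n_long_reads: int = 2000
    truncation_fraction: float = 0.0
    min_truncation: int = 200
    max_truncation: int = 500
    clip_max: int = 20
    overclip_fraction: float = 0.05  # fraction with a clip exceeding 100 nt

    cage_reads_per_tss: int = 8
    cage_jitter_sd: float = 0.0
    cage_read_length: int = 30
    pas_reads_per_site: int = 8
    pas_read_length: int = 30
    polya_tail_range: tuple[int, int] = (5, 15)
    n_internal_priming_traps: int = 5
    trap_a_run_length: int = 8
    trap_reads_per_site: int = 4

    n_rpfs: int = 3000
    rpf_in_frame_fraction: float = 0.8
    rpf_length_range: tuple[int, int] = (26, 32)

    def __post_init__(self) -> None:
        for name in (
            "p_alt_tss",
            "p_alt_splice",
            "p_apa",
            "novel_gene_fraction",
            "sr_only_fraction",
            "truncation_fraction",
            "overclip_fraction",
            "rpf_in_frame_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_alt_tss + self.p_alt_splice + self.p_apa - 1.0) > 1e-9:
            raise ValueError("isoform-variant probabilities must sum to 1")


@dataclass(frozen=True)
class ReadLabel:
    read_id: str
    isoform_id: str
    truncated: bool
    truncation_length: int
    clip5: int
    clip3: int


@dataclass(frozen=True)
class PasReadLabel:
    read_id: str
    kind: str  # genuine | trap
    isoform_id: Optional[str]
    site: int  # true cleavage site (genuine) or mispriming boundary (trap)


@dataclass(frozen=True)
class RpfLabel:
    rpf_id: str
    transcript_id: str
    in_frame: bool


@dataclass
class GroundTruth:
    """Everything the generator knows, for use as a test oracle."""

    genome: dict[str, str]
    transcriptome: Transcriptome  # all true isoforms
    isoform_class: dict[str, str]  # transcript_id -> refseq | sr_only | novel
    refseq: Transcriptome
    sr_assembly: Transcriptome
    tss_sites: dict[str, int]  # transcript_id -> true TSS boundary coordinate
    pas_sites: dict[str, int]  # transcript_id -> true cleavage boundary coordinate
    trap_positions: list[tuple[str, int]]  # (isoform_id, transcript-space A-run start)

    read_labels: list[ReadLabel] = field(default_factory=list)
    pas_read_labels: list[PasReadLabel] = field(default_factory=list)
    cage_tag_truth: list[tuple[str, int]] = field(default_factory=list)  # (read_id, tag pos)
    rpf_labels: list[RpfLabel] = field(default_factory=list)

    def expressed_isoform_keys(self, max_clip: int = 100) -> set[tuple]:
        """Identity keys of isoforms with >= 1 intact, unclipped read.

        The key is what the pipeline can recover: chrom, strand, intron
        chain and the two end boundary coordinates.
        """
        expressed = {
            lab.isoform_id
            for lab in self.read_labels
            if not lab.truncated and lab.clip5 <= max_clip and lab.clip3 <= max_clip
        }
        return {self.isoform_key(tid) for tid in expressed}

    def isoform_key(self, transcript_id: str) -> tuple:
        t = self.transcriptome[transcript_id]
        return (t.chrom, t.strand, intron_chain(t), t.five_prime, t.three_prime)


# ---------------------------------------------------------------------------
# Reference simulation


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


class _GenomeEditor:
    """Mutable genome with transcript-space write access."""

    def __init__(self, seq: str) -> None:
        self.seq = list(seq)

    def write_genomic(self, pos: int, bases: str) -> None:
        self.seq[pos : pos + len(bases)] = list(bases)

    def write_transcript(self, t: TranscriptModel, pos: int, bases: str) -> None:
        """Write ``bases`` (transcript orientation) at transcript coordinate pos."""
        from .annotation import reverse_complement

        for i, b in enumerate(bases):
            g = transcript_to_genomic(t, pos + i)
            self.seq[g] = b if t.strand == "+" else reverse_complement(b)

    def __str__(self) -> str:
        return "".join(self.seq)


_NONSTOP_CODONS = [
    c
    for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA", "ATG")
]


def simulate_reference(config: SimConfig) -> GroundTruth:
    """Build the toy genome, true transcriptome, annotated subset and SR assembly."""
    rng = np.random.default_rng(config.seed)
    genes: list[list[TranscriptModel]] = []
    cursor = config.intergenic_gap
    genome_parts: list[int] = []  # gene span ends, for sizing

    iso_counter = 0
    for g in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons: list[GenomicInterval] = []
        pos = cursor
        for i in range(n_exons):
            lo, hi = (
                config.terminal_exon_length
                if i in (0, n_exons - 1)
                else config.internal_exon_length
            )
            length = int(rng.integers(lo, hi + 1))
            exons.append(GenomicInterval(CHROM, pos, pos + length, strand))
            pos += length + int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        gene_id = f"gene_{g + 1}"
        iso_counter += 1
        base = TranscriptModel(f"iso_{iso_counter}", gene_id, CHROM, strand, tuple(exons))
        isoforms = [base]

        n_iso = int(
            rng.integers(config.min_isoforms_per_gene, config.max_isoforms_per_gene + 1)
        )
        is_novel_gene = g < round(config.n_genes * config.novel_gene_fraction)
        skippable = list(range(1, n_exons - 1))
        # distinct end variants must stay resolvable: alternative TSS/polyA
        # positions of one gene are kept >= 150 nt apart (beyond the peak
        # gap, the support window and the TSS-polyA linkage distance)
        used_tss_deltas = [0]
        used_apa_deltas = [0]

        def _pick_delta(used: list[int], exon_length: int) -> Optional[int]:
            hi = exon_length - 100
            if hi <= 150:
                return None
            for _ in range(20):
                delta = int(rng.integers(150, hi))
                if all(abs(delta - u) >= 150 for u in used):
                    used.append(delta)
                    return delta
            return None

        for _ in range(n_iso - 1):
            kind = rng.choice(
                ["alt_tss", "alt_splice", "apa"],
                p=[config.p_alt_tss, config.p_alt_splice, config.p_apa],
            )
            if is_novel_gene:
                # novel loci vary by splicing only, so each novel isoform has
                # a distinct intron chain the rescue step can recover
                if not skippable:
                    continue
                kind = "alt_splice"
            if kind == "alt_splice" and not skippable:
                kind = "apa"
            iso_counter += 1
            tid = f"iso_{iso_counter}"
            if kind == "alt_splice":
                skip = skippable.pop(int(rng.integers(0, len(skippable))))
                new_exons = tuple(e for i, e in enumerate(base.exons) if i != skip)
                variant = TranscriptModel(tid, gene_id, CHROM, strand, new_exons)
            elif kind == "alt_tss":
                first_exon = base.exons[0] if strand == "+" else base.exons[-1]
                delta = _pick_delta(used_tss_deltas, len(first_exon))
                if delta is None:
                    iso_counter -= 1
                    continue
                ex = list(base.exons)
                if strand == "+":
                    first = ex[0]
                    ex[0] = GenomicInterval(CHROM, first.start + delta, first.end, strand)
                else:
                    last = ex[-1]
                    ex[-1] = GenomicInterval(CHROM, last.start, last.end - delta, strand)
                variant = TranscriptModel(tid, gene_id, CHROM, strand, tuple(ex))
            else:  # apa
                last_exon = base.exons[-1] if strand == "+" else base.exons[0]
                delta = _pick_delta(used_apa_deltas, len(last_exon))
                if delta is None:
                    iso_counter -= 1
                    continue
                ex = list(base.exons)
                if strand == "+":
                    last = ex[-1]
                    ex[-1] = GenomicInterval(CHROM, last.start, last.end - delta, strand)
                else:
                    first = ex[0]
                    ex[0] = GenomicInterval(CHROM, first.start + delta, first.end, strand)
                variant = TranscriptModel(tid, gene_id, CHROM, strand, tuple(ex))
            key = (intron_chain(variant), variant.five_prime, variant.three_prime)
            if any(
                (intron_chain(x), x.five_prime, x.three_prime) == key for x in isoforms
            ):
                iso_counter -= 1
                continue
            isoforms.append(variant)
        genes.append(isoforms)
        cursor = pos + config.intergenic_gap
        genome_parts.append(pos)

    genome_len = cursor + config.intergenic_gap
    editor = _GenomeEditor(_rand_seq(rng, genome_len))

    # classes: novel genes first (deterministic), then per-isoform sr_only draws
    isoform_class: dict[str, str] = {}
    n_novel = round(config.n_genes * config.novel_gene_fraction)
    for g, isoforms in enumerate(genes):
        for i, t in enumerate(isoforms):
            if g < n_novel:
                isoform_class[t.transcript_id] = "novel"
            elif i > 0 and rng.random() < config.sr_only_fraction:
                isoform_class[t.transcript_id] = "sr_only"
            else:
                isoform_class[t.transcript_id] = "refseq"

    all_iso = [t for isoforms in genes for t in isoforms]

    # Embed a clean ORF into every gene's primary isoform (transcript space):
    # ATG + stop-free codons + TAA spanning roughly the middle 45% of the
    # transcript, so ribosome-footprint phasing has a well-defined frame.
    for isoforms in genes:
        base = isoforms[0]
        L = base.length
        orf_start = int(0.3 * L)
        orf_len = (int(0.45 * L) // 3) * 3
        body = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=orf_len // 3 - 2)
        )
        editor.write_transcript(base, orf_start, "ATG" + body + "TAA")

    # Force the two transcript-terminal bases of every isoform to be non-A so
    # a genuine polyA tail is never genome-templated at the cleavage site.
    for t in all_iso:
        editor.write_transcript(t, t.length - 2, "GC")
        # and the two genomic bases just past the cleavage site (transcript
        # orientation) must not extend an A run
        if t.strand == "+":
            g = t.exons[-1].end
            editor.write_genomic(g, "CT")
        else:
            g = t.exons[0].start
            editor.write_genomic(max(g - 2, 0), "AG")  # revcomp 'CT'

    # Internal-priming traps: genomic A-runs in 3'UTR-like interiors of the
    # last exon of selected primary isoforms, flanked by non-A bases.
    trap_positions: list[tuple[str, int]] = []
    trap_candidates = [isoforms[0] for isoforms in genes]
    order = rng.permutation(len(trap_candidates))
    for idx in order[: config.n_internal_priming_traps]:
        t = trap_candidates[int(idx)]
        run = config.trap_a_run_length
        pos = t.length - 2 - 40 - run  # inside the terminal exon, clear of ends
        editor.write_transcript(t, pos - 1, "C" + "A" * run + "C")
        trap_positions.append((t.transcript_id, pos))
    trap_positions.sort()

    genome = {CHROM: str(editor)}

    truth_tome = Transcriptome()
    refseq = Transcriptome()
    sr = Transcriptome()
    tss_sites: dict[str, int] = {}
    pas_sites: dict[str, int] = {}
    for t in all_iso:
        cds = longest_orf(transcript_sequence(t, genome), min_length=120)
        t = replace(t, cds=cds)
        truth_tome.add(t)
        tss_sites[t.transcript_id] = t.five_prime
        pas_sites[t.transcript_id] = t.three_prime
        cls = isoform_class[t.transcript_id]
        if cls == "refseq":
            refseq.add(t)
            sr.add(replace(t, transcript_id="sr_" + t.transcript_id))
        elif cls == "sr_only":
            sr.add(replace(t, transcript_id="sr_" + t.transcript_id))

    return GroundTruth(
        genome=genome,
        transcriptome=truth_tome,
        isoform_class=isoform_class,
        refseq=refseq,
        sr_assembly=sr,
        tss_sites=tss_sites,
        pas_sites=pas_sites,
        trap_positions=trap_positions,
    )


# ---------------------------------------------------------------------------
# Long reads


def _truncate_blocks(
    t: TranscriptModel, cut: int
) -> tuple[tuple[int, int], ...]:
    """Blocks of a read missing the first ``cut`` nt of transcript sequence."""
    remaining = t.length - cut
    exon_iter = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    blocks: list[tuple[int, int]] = []
    skip = cut
    for e in exon_iter:
        if skip >= len(e):
            skip -= len(e)
            continue
        if t.strand == "+":
            blocks.append((e.start + skip, e.end))
        else:
            blocks.append((e.start, e.end - skip))
        skip = 0
    assert sum(b[1] - b[0] for b in blocks) == remaining
    return tuple(sorted(blocks))


def simulate_long_reads(
    truth: GroundTruth, config: SimConfig
) -> tuple[list[AlignedLongRead], list[ReadLabel]]:
    """Sample intact and 5'-truncated long reads from the true isoforms."""
    rng = np.random.default_rng(config.seed + 1)
    isoforms = list(truth.transcriptome)
    picks = rng.integers(0, len(isoforms), size=config.n_long_reads)
    reads: list[AlignedLongRead] = []
    labels: list[ReadLabel] = []
    for i, k in enumerate(picks):
        t = isoforms[int(k)]
        rid = f"lr_{i + 1}"
        truncated = bool(rng.random() < config.truncation_fraction)
        cut = 0
        if truncated:
            hi = min(config.max_truncation, t.length - 100)
            cut = int(rng.integers(config.min_truncation, max(hi, config.min_truncation) + 1))
            blocks = _truncate_blocks(t, cut)
        else:
            blocks = tuple((e.start, e.end) for e in t.exons)
        clip5 = int(rng.integers(0, config.clip_max + 1))
        clip3 = int(rng.integers(0, config.clip_max + 1))
        if rng.random() < config.overclip_fraction:
            if rng.random() < 0.5:
                clip5 = int(rng.integers(101, 251))
            else:
                clip3 = int(rng.integers(101, 251))
        reads.append(AlignedLongRead(rid, t.chrom, t.strand, blocks, clip5, clip3))
        labels.append(ReadLabel(rid, t.transcript_id, truncated, cut, clip5, clip3))
    truth.read_labels = labels
    return reads, labels


# ---------------------------------------------------------------------------
# End evidence


def simulate_end_evidence(
    truth: GroundTruth, config: SimConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Raw CAGE and PAS reads as (read_id, sequence) pairs, with labels.

    CAGE reads: 'GG' + transcript 5' sequence at the TSS (+- Gaussian
    jitter).  Genuine PAS reads: GGG-like prefix + the sequence upstream of
    the true cleavage site + a 5-15 nt non-templated A tail.  Trap reads:
    same structure but primed at a genomic A-run, so their tail is
    templated and the tailed variant places on the genome.
    """
    rng = np.random.default_rng(config.seed + 2)
    genome = truth.genome
    cage: list[tuple[str, str]] = []
    pas: list[tuple[str, str]] = []
    cage_truth: list[tuple[str, int]] = []
    pas_labels: list[PasReadLabel] = []

    # one CAGE/PAS site per distinct (gene, boundary) position
    seen_tss: set[tuple[str, int]] = set()
    seen_pas: set[tuple[str, int]] = set()
    n_cage = 0
    n_pas = 0
    for t in truth.transcriptome:
        seq = transcript_sequence(t, genome)
        tss_key = (t.gene_id, t.five_prime)
        if tss_key not in seen_tss:
            seen_tss.add(tss_key)
            for _ in range(config.cage_reads_per_tss):
                n_cage += 1
                jitter = int(round(rng.normal(0.0, config.cage_jitter_sd)))
                jitter = max(0, min(jitter, t.length - config.cage_read_length - 1))
                insert = seq[jitter : jitter + config.cage_read_length]
                rid = f"cage_{n_cage}"
                cage.append((rid, "GG" + insert))
                shift = jitter if t.strand == "+" else -jitter
                cage_truth.append((rid, t.five_prime + shift))
        pas_key = (t.gene_id, t.three_prime)
        if pas_key not in seen_pas:
            seen_pas.add(pas_key)
            for _ in range(config.pas_reads_per_site):
                n_pas += 1
                tail = int(rng.integers(config.polya_tail_range[0], config.polya_tail_range[1] + 1))
                upstream = seq[t.length - config.pas_read_length : t.length]
                rid = f"pas_{n_pas}"
                pas.append((rid, "GGG" + upstream + "A" * tail))
                pas_labels.append(PasReadLabel(rid, "genuine", t.transcript_id, t.three_prime))

    for tid, run_start in truth.trap_positions:
        t = truth.transcriptome[tid]
        seq = transcript_sequence(t, genome)
        for _ in range(config.trap_reads_per_site):
            n_pas += 1
            n_templated_a = min(config.trap_a_run_length, 6)
            upstream = seq[run_start - config.pas_read_length : run_start]
            rid = f"pas_{n_pas}"
            pas.append((rid, "GGG" + upstream + "A" * n_templated_a))
            site = transcript_to_genomic(t, run_start - 1)
            site = site + 1 if t.strand == "+" else site
            pas_labels.append(PasReadLabel(rid, "trap", tid, site))

    truth.cage_tag_truth = cage_truth
    truth.pas_read_labels = pas_labels
    return cage, pas


# ---------------------------------------------------------------------------
# Ribosome footprints


def simulate_rpfs(
    truth: GroundTruth, config: SimConfig
) -> tuple[list[RpfPlacement], list[RpfLabel]]:
    """Footprints over ORF-bearing isoforms with a controlled in-frame fraction.

    The in-frame fraction of 5' ends sits at codon starts within the ORF;
    the remainder is uniform over the transcript.  Lengths are uniform over
    the inclusive selection window.
    """
    rng = np.random.default_rng(config.seed + 3)
    targets = [
        t
        for t in truth.transcriptome
        if t.cds is not None and (t.cds[1] - t.cds[0]) >= 150
    ]
    if not targets:
        raise ValueError("no isoforms with a usable ORF")
    picks = rng.integers(0, len(targets), size=config.n_rpfs)
    lmin, lmax = config.rpf_length_range
    placements: list[RpfPlacement] = []
    labels: list[RpfLabel] = []
    for i, k in enumerate(picks):
        t = targets[int(k)]
        orf_start, orf_end = t.cds  # type: ignore[misc]
        length = int(rng.integers(lmin, lmax + 1))
        in_frame = bool(rng.random() < config.rpf_in_frame_fraction)
        if in_frame:
            n_codons = (orf_end - orf_start - length) // 3
            pos = orf_start + 3 * int(rng.integers(0, max(n_codons, 1)))
        else:
            pos = int(rng.integers(0, t.length - length))
        rid = f"rpf_{i + 1}"
        placements.append(RpfPlacement(t.transcript_id, pos, length))
        labels.append(RpfLabel(rid, t.transcript_id, in_frame))
    truth.rpf_labels = labels
    return placements, labels


# ---------------------------------------------------------------------------
# End-to-end convenience + evaluation


def simulate_all(
    config: SimConfig,
) -> tuple[GroundTruth, list[AlignedLongRead], list[tuple[str, str]], list[tuple[str, str]]]:
    """Reference + long reads + raw end-evidence reads, in one call."""
    truth = simulate_reference(config)
    reads, _ = simulate_long_reads(truth, config)
    cage, pas = simulate_end_evidence(truth, config)
    return truth, reads, cage, pas


def evaluate_recovery(
    result: AssemblyResult,
    truth: GroundTruth,
    max_clip: int = 100,
    end_tolerance: int = 0,
) -> dict:
    """Precision/recall of the assembled isoforms against the expressed truth.

    Isoforms are identified by (chrom, strand, intron chain, 5' boundary,
    3' boundary); the truth set is restricted to isoforms with at least one
    intact read surviving the clip filter.  ``end_tolerance`` relaxes the
    end comparison (chains stay exact), for runs with jittered evidence.
    """
    truth_keys = truth.expressed_isoform_keys(max_clip=max_clip)
    found_keys = {
        (
            iso.model.chrom,
            iso.model.strand,
            intron_chain(iso.model),
            iso.model.five_prime,
            iso.model.three_prime,
        )
        for iso in result.isoforms
    }

    def matches(k1: tuple, k2: tuple) -> bool:
        return (
            k1[:3] == k2[:3]
            and abs(k1[3] - k2[3]) <= end_tolerance
            and abs(k1[4] - k2[4]) <= end_tolerance
        )

    if end_tolerance == 0:
        tp_found = found_keys & truth_keys
        tp_truth = tp_found
    else:
        tp_found = {f for f in found_keys if any(matches(f, t) for t in truth_keys)}
        tp_truth = {t for t in truth_keys if any(matches(f, t) for f in found_keys)}
    precision = len(tp_found) / len(found_keys) if found_keys else 0.0
    recall = len(tp_truth) / len(truth_keys) if truth_keys else 0.0
    return {
        "n_truth": len(truth_keys),
        "n_found": len(found_keys),
        "true_positives": len(tp_truth),
        "precision": precision,
        "recall": recall,
    }


def truncated_only_chains(result: AssemblyResult, truth: GroundTruth) -> list[str]:
    """Emitted isoforms whose intron chain belongs to no true isoform.

    Under the truncation noise model these would be decay-intermediate
    chains leaking through the pipeline; the expected value is none.
    """
    true_chains = {
        (t.chrom, t.strand, intron_chain(t)) for t in truth.transcriptome
    }
    return [
        iso.model.transcript_id
        for iso in result.isoforms
        if (iso.model.chrom, iso.model.strand, intron_chain(iso.model)) not in true_chains
    ]


# ---------------------------------------------------------------------------
# File emission


def write_simulation(
    outdir: str,
    truth: GroundTruth,
    reads: Sequence[AlignedLongRead],
    cage: Sequence[tuple[str, str]],
    pas: Sequence[tuple[str, str]],
) -> None:
    """Emit the full simulation as standard text formats."""
    import os

    from .annotation import write_annotation, write_fasta
    from .pipeline import write_sam

    os.makedirs(outdir, exist_ok=True)
    write_fasta(truth.genome, os.path.join(outdir, "genome.fa"))
    write_annotation(truth.transcriptome, os.path.join(outdir, "truth.gtf"))
    write_annotation(truth.refseq, os.path.join(outdir, "refseq.gtf"))
    write_annotation(truth.sr_assembly, os.path.join(outdir, "sr_assembly.gtf"))
    write_sam(reads, truth.genome, os.path.join(outdir, "long_reads.sam"))
    for name, rows in (("cage.fastq", cage), ("pas.fastq", pas)):
        with open(os.path.join(outdir, name), "w") as fh:
            for rid, seq in rows:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(os.path.join(outdir, "read_labels.tsv"), "w") as fh:
        fh.write("read_id\tisoform_id\ttruncated\ttruncation_length\tclip5\tclip3\n")
        for lab in truth.read_labels:
            fh.write(
                f"{lab.read_id}\t{lab.isoform_id}\t{int(lab.truncated)}\t"
                f"{lab.truncation_length}\t{lab.clip5}\t{lab.clip3}\n"
            )
    with open(os.path.join(outdir, "pas_read_labels.tsv"), "w") as fh:
        fh.write("read_id\tkind\tisoform_id\tsite\n")
        for plab in truth.pas_read_labels:
            fh.write(f"{plab.read_id}\t{plab.kind}\t{plab.isoform_id or '.'}\t{plab.site}\n")
    with open(os.path.join(outdir, "isoform_classes.tsv"), "w") as fh:
        fh.write("transcript_id\tclass\ttss\tpas\n")
        for t in truth.transcriptome:
            fh.write(
                f"{t.transcript_id}\t{truth.isoform_class[t.transcript_id]}\t"
                f"{truth.tss_sites[t.transcript_id]}\t{truth.pas_sites[t.transcript_id]}\n"
            )
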