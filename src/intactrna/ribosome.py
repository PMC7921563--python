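"""Ribosome-profiling evidence: RPF selection, distance spectrum,
periodogram, and trimmed-mean metagene profiles.

Ribosome-protected fragments (RPFs) are the 26-32 nt footprints of
translating ribosomes.  Because elongating ribosomes step one codon at a
time, the 5' ends of RPFs on a translated ORF are phased: the spectrum of
pairwise 5'-end distances shows a 3-nt comb, and its discrete-Fourier
periodogram a dominant period of 3 nt.  An annotated ORF is not a
prerequisite for the spectrum itself.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RpfPlacement:
    """An RPF alignment in transcript coordinates."""

    transcript_id: str
    five_prime_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.length < 1:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class DistanceSpectrum:
    """Counts of inter-5'-end distances d = 0..max_distance, per transcript pairs."""

    counts: tuple[int, ...]

    @property
    def max_distance(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class PeriodogramResult:
    frequencies: tuple[float, ...]
    density: tuple[float, ...]
    relative_density: tuple[float, ...]
    dominant_period: Optional[float]


@dataclass(frozen=True)
class MetageneProfile:
    """10%-trimmed-mean signal over length-normalized 5'UTR / ORF / 3'UTR."""

    values: tuple[float, ...]
    segment_lengths: tuple[int, int, int]  # median 5'UTR, ORF, 3'UTR lengths
    n_transcripts: int

    @property
    def segments(self) -> tuple[str, ...]:
        u5, orf, u3 = self.segment_lengths
        return tuple(["utr5"] * u5 + ["orf"] * orf + ["utr3"] * u3)


def select_rpfs(
    placements: Iterable[RpfPlacement], min_length: int = 26, max_length: int = 32
) -> list[RpfPlacement]:
    """Retain RPFs with lengths in the inclusive 26-32 nt window."""
    return [p for p in placements if min_length <= p.length <= max_length]


def distance_spectrum(
    placements: Iterable[RpfPlacement], max_distance: int = 100
) -> DistanceSpectrum:
    """5'-end overlap analysis: count downstream-minus-upstream distances
    between all pairs of distinct RPF 5' ends on the same transcript.

    Self-pairs are excluded; coincident distinct reads contribute to d = 0.
    Cross-transcript pairs are never counted.
    """
    counts = np.zeros(max_distance + 1, dtype=np.int64)
    per_transcript: dict[str, list[int]] = defaultdict(list)
    for p in placements:
        per_transcript[p.transcript_id].append(p.five_prime_pos)
    for positions in per_transcript.values():
        pos_counts: dict[int, int] = defaultdict(int)
        for x in positions:
            pos_counts[x] += 1
        uniq = sorted(pos_counts)
        for i, x in enumerate(uniq):
            cx = pos_counts[x]
            if cx > 1:
                counts[0] += cx * (cx - 1) // 2
            for y in uniq[i + 1 :]:
                d = y - x
                if d > max_distance:
                    break
                counts[d] += cx * pos_counts[y]
    return DistanceSpectrum(tuple(int(c) for c in counts))


def periodogram(spectrum: DistanceSpectrum) -> PeriodogramResult:
    """Discrete-Fourier periodogram of the mean-centered distance spectrum.

    Density at frequency k/N (k = 1..N//2) is |X_k|^2 / N of the centered
    series; the relative density normalizes to the value at the first
    reported frequency.  The dominant period is 1/argmax frequency, or
    ``None`` for a flat (constant) spectrum.
    """
    x = np.asarray(spectrum.counts, dtype=float)
    if len(x) < 8:
        raise ValueError("spectrum too short for a periodogram (need >= 8 positions)")
    if not np.any(x):
        raise ValueError("all-zero distance spectrum: no signal")
    n = len(x)
    centered = x - x.mean()
    fft = np.fft.rfft(centered)
    ks = np.arange(1, n // 2 + 1)
    density = (np.abs(fft[ks]) ** 2) / n
    freqs = ks / n
    if np.max(density) < 1e-12:
        return PeriodogramResult(
            tuple(freqs), tuple(density), tuple(np.zeros_like(density)), None
        )
    rel = density / density[0] if density[0] > 0 else density / np.max(density)
    dominant = 1.0 / freqs[int(np.argmax(density))]
    return PeriodogramResult(tuple(freqs), tuple(density), tuple(rel), float(dominant))


def _rescale_nearest(values: np.ndarray, target_len: int) -> np.ndarray:
    """Nearest-position resampling of a 1D signal to ``target_len``.

    Target position j samples source index round(j * (L-1) / (M-1)) for
    M > 1, and index 0 for M == 1.
    """
    src_len = len(values)
    if src_len == 0 or target_len == 0:
        return np.zeros(target_len)
    if target_len == 1:
        idx = np.array([0])
    else:
        idx = np.rint(np.arange(target_len) * (src_len - 1) / (target_len - 1)).astype(int)
    return values[idx]


def metagene_profile(
    per_transcript_signal: Mapping[str, Sequence[float]],
    cds_map: Mapping[str, tuple[int, int]],
    trim_fraction: float = 0.10,
) -> MetageneProfile:
    """Aggregate per-transcript signal into a metagene profile.

    Each transcript's 5'UTR, ORF and 3'UTR segments are rescaled (nearest-
    position sampling) to the median segment lengths across transcripts and
    aggregated per position with a trimmed mean that discards the
    ``floor(trim_fraction * n)`` lowest and highest values.  Transcripts
    without an ORF annotation, or with an empty segment, are excluded.
    """
    rows: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    seg_lengths: list[tuple[int, int, int]] = []
    for tid, signal in per_transcript_signal.items():
        cds = cds_map.get(tid)
        if cds is None:
            log.info("metagene: %s has no ORF, excluded", tid)
            continue
        sig = np.asarray(signal, dtype=float)
        s, e = cds
        if not (0 < s < e < len(sig)):
            log.info("metagene: %s has an empty segment, excluded", tid)
            continue
        rows.append((sig[:s], sig[s:e], sig[e:]))
        seg_lengths.append((s, e - s, len(sig) - e))
    if not rows:
        raise ValueError("no transcripts with usable ORF annotation")

    medians = tuple(int(round(float(np.median([sl[i] for sl in seg_lengths])))) for i in range(3))
    stacked = np.stack(
        [
            np.concatenate([_rescale_nearest(seg, m) for seg, m in zip(row, medians)])
            for row in rows
        ]
    )
    profile = stats.trim_mean(stacked, trim_fraction, axis=0)
    return MetageneProfile(tuple(float(v) for v in profile), medians, len(rows))


# ---------------------------------------------------------------------------
# I/O


def read_rpf_bed(path: str) -> list[RpfPlacement]:
    """BED of transcript-space RPF alignments: chrom column = transcript id,
    start = 5'-end position, end - start = fragment length."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tid, start, end = parts[0], int(parts[1]), int(parts[2])
            out.append(RpfPlacement(tid, start, end - start))
    return out


def write_rpf_bed(placements: Sequence[RpfPlacement], path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(placements):
            fh.write(
                f"{p.transcript_id}\t{p.five_prime_pos}\t{p.five_prime_pos + p.length}\trpf_{i}\t0\t+\n"
            )


def write_spectrum_tsv(spectrum: DistanceSpectrum, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("distance\tcount\n")
        for d, c in enumerate(spectrum.counts):
            fh.write(f"{d}\t{c}\n")


def write_periodogram_tsv(result: PeriodogramResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("frequency\tdensity\trelative_density\n")
        for f, d, r in zip(result.frequencies, result.density, result.relative_density):
            fh.write(f"{f:.6f}\t{d:.6g}\t{r:.6g}\n")


def write_metagene_tsv(profile: MetageneProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\tsegment\tvalue\n")
        for i, (seg, v) in enumerate(zip(profile.segments, profile.values)):
            fh.write(f"{i}\t{seg}\t{v:.6g}\n")
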