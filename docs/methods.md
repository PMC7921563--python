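# Methods

## Intactness model

A long read is treated as *intact* when three independent conditions hold:
its alignment is essentially full-length (soft/hard clips ≤ 100 nt at each
end — the boundary is inclusive, reading the rule as "longer than 100 nt
filtered"), its splice structure is corroborated, and both of its ends are
corroborated. Splice corroboration is **intron-chain equality**: the
ordered list of (donor, acceptor) junction coordinates must equal that of
an annotated or short-read-assembled isoform, with end coordinates left
completely unconstrained. Chain *containment* is deliberately not accepted
as support: a 5′-truncated read whose remaining junctions form a suffix of
a real chain would otherwise count as evidence for the very artifact the
pipeline exists to remove. The same end-agnostic chain-equality criterion
is reused for validation counts from a second long-read platform.

End corroboration is a disjunction per end: the read's genomic 5′ end lies
within a CAGE peak (extended by the support window) or within the window of
an annotated TSS; the 3′ end analogously with PAS cleavage sites or
annotated 3′ ends. Evidence on the opposite strand never supports. When
both evidence kinds are available for an end, the experimental evidence
(CAGE/PAS) wins by default and the end is corrected to it; this is a
configuration switch (`prefer_evidence`).

Coordinates are 0-based half-open throughout; transcript "end coordinates"
are boundary coordinates (plus-strand 5′ end = first exon start,
minus-strand 5′ end = last exon end), so CAGE/PAS tags, peak modes, read
ends and annotated ends all live on one consistent scale.

## Read-level evidence filters

* CAGE: retain reads whose second base is G (the `NG`/`GG` cap signature —
  the listed alternates `NG` and `GG` reduce to exactly this predicate),
  trim the two template-switching guanosines, keep uniquely placed reads of
  ≥ 18 nt after trimming. The mapped 5′ end is the TSS tag.
* PAS: retain reads whose first three bases match `GGG`/`NGG`/`NNG`/`GNG`
  (N = any base; the union is "third base G", but the predicate is written
  against the four listed patterns) and that end with ≥ 3 adenosines. The
  *maximal terminal A-run* defines the tail; internal A's are untouched.
  Both the tailless and the tailed variant are placed on the genome. Any
  placement of the tailed variant ⇒ internal priming, discarded — including
  a tailed placement at a different locus than the tailless one, which is
  the conservative reading. The tailless 3′ end is the cleavage site.
* Placement on the toy genomes uses exact unique string search over both
  strands (`exact_place`); ambiguous probes are dropped. This stands in
  for a short-read aligner at synthetic scale and is exactly what the
  internal-priming test needs: "does the tailed sequence occur anywhere?".

## Peak calling

End tags are clustered per chrom/strand by single-linkage runs: positions
whose sorted neighbours differ by ≤ `max_gap` (default 20 nt) form one
candidate peak, candidates with total count < `min_count` (default 2) are
dropped, and the mode is the highest-count position with a 5′-most
(strand-aware) tie-break. This is the simplest deterministic scheme that
produces what the pipeline needs — positional peaks with counts and a
representative mode — and both parameters are exposed.

## Novel-isoform rescue and TSS–polyA isoforms

Unmatched reads with CAGE 5′ support are grouped by identical intron chain
(junction-free reads, which carry no chain, are grouped by their shared
CAGE-peak/PAS-site evidence pair instead). Groups of ≥ 2 reads with at
least one PAS-supported 3′ end become novel isoforms: junction coordinates
are per-junction modal values, terminal boundaries come from end
correction, and interior block edges from the widest supporting read.

Each final isoform's full-length CAGE-supported reads define coordinate
pairs (CAGE peak mode, read 3′ end) — the peak mode, not the raw read 5′
end, since the peak is the better TSS estimate. Pairs are clustered by
single linkage under Chebyshev distance ≤ 100 nt (default); each cluster is
one TSS–polyA isoform with modal coordinates and its read count. Modal
ties break toward the smaller coordinate for determinism.

## Ribosome-footprint periodicity

Footprints of 26–32 nt (inclusive) are kept. The distance spectrum counts,
per transcript, downstream-minus-upstream distances between all pairs of
distinct footprint 5′ ends up to D = 100 nt; self-pairs are excluded while
coincident distinct reads do contribute to d = 0, and pairs are never
formed across transcripts (cross-transcript distances are meaningless in
transcript coordinates). The periodogram is |DFT|²/N of the mean-centered
count series at frequencies k/N, k = 1…⌊N/2⌋; mean-centering removes the
zero-frequency term that would otherwise mask the periodicity, and the
relative density normalizes to the first reported (lowest non-zero)
frequency. With the default D = 100 the frequency grid has no point at
exactly 1/3, so a perfectly phased library reports a dominant period of
1/(34/102) ≈ 2.97 nt; this grid quantization is inherent to the
presentation and left as computed. A flat (constant) spectrum has no
dominant frequency and is reported as such; an all-zero spectrum is an
error.

Metagene profiles rescale each transcript's 5′UTR/ORF/3′UTR segments to the
median segment lengths (nearest-position sampling: target position j reads
source index round(j·(L−1)/(M−1))) and aggregate per position with a
trimmed mean that discards ⌊trim·n⌋ values from each side (trim = 0.10).
Transcripts without an ORF, or with an empty segment, are excluded and
logged. ORFs are the longest AUG-initiated reading frame ending in a stop,
ties broken 5′-most, minimum length 30 nt (configurable; no published
value to follow).

## Cross-species overlap and purity regression

Overlap is computed over the universe of shared genes, counted at the
species-A gene level. A gene overlaps iff *any* of its homologs is in the
other species' set — one-to-many homology is what lets the two directional
fractions differ (e.g. 562/1,885 one way but 641/1,385 the other).
Enrichment is the upper hypergeometric tail computed from log-factorials
(`scipy.special.gammaln` + `logsumexp`), exact in log space for p-values
far below float underflow. The exact construction of a published 2×2
table from a one-to-many homolog map is underdetermined, so the table
direction is configurable and the p-value itself is reported, not asserted.

The purity regression normalizes each cell's counts to unit sum, takes the
gene-wise median per cluster as its consensus profile, restricts to genes
present and nonzero in the bulk profile and in every cluster column, and
fits ordinary least squares of bulk on clusters (statsmodels). R² is about
the mean of Y when an intercept is fitted (the default; a no-intercept
variant with uncentered R² is available since neither convention is
documented for the original analysis). Rank-deficient designs are fitted
via the pseudoinverse and flagged.

## The synthetic-data generator

The generator emulates the study conditions the pipeline targets, and its
defaults are those conditions: 20 genes (≈ 40–55 isoforms with up to 4 per
gene), 2,000 long reads, 25 % of genes withheld from the annotation as
novel loci, 8 CAGE reads per TSS and 8 PAS reads per cleavage site, 5
internal-priming traps (8-nt genomic A-runs in terminal-exon interiors with
4 reads each), 3,000 footprints at 80 % in-frame. Isoform variants are
drawn as 50 % alternative polyadenylation, 30 % exon skipping, 20 %
alternative TSS — polyadenylation-dominant, mirroring the variant mix
reported for tissue-specific transcriptomes.

Constraints the generator enforces so that ground truth is recoverable in
the noise-free setting:

* genes are separated by ≥ 600 nt and alternative TSS/polyA positions of
  one gene by ≥ 150 nt, beyond the peak gap (20), the support window (50)
  and the TSS–polyA linkage distance (100) — closer sites are physically
  unresolvable by the clustering parameters, which would make "exact
  recovery" an ill-posed target rather than a property of the pipeline;
* novel genes vary by splicing only, so every withheld isoform has a
  distinct intron chain the rescue step can in principle recover;
* transcript-terminal bases and the bases just past each cleavage site are
  forced non-A, so a genuine 5–15 nt non-templated tail can never be
  genome-templated by accident; trap A-runs are flanked by non-A bases so
  the run length is exact;
* a clean ORF (ATG + stop-free codons + TAA, ≈ 45 % of transcript length)
  is written into each gene's primary isoform; recorded ORFs are whatever
  the ORF finder reports after all genome edits, keeping truth and code
  self-consistent.

What the generator does **not** emulate: base-calling errors on long reads
(the pipeline consumes error-corrected alignments; junction tolerance is
the configurable surrogate), expression-level realism, overlapping genes,
and upstream (5′-ward) CAGE jitter — the Gaussian jitter is clamped into
the transcript, making it effectively downstream. Passing tests therefore
show the pipeline's logic is correct under its stated assumptions, not that
it is robust to aligner artifacts or complex loci.

5′ truncations remove ≥ 200 nt (up to 500), deleting junctions the cut
passes; clip lengths are uniform 0–20 nt with a configurable fraction
(default 5 %) exceeding 100 nt to exercise the clip filter. All sampling
flows from a single mandatory seed (three fixed sub-streams for reference,
reads, and evidence), so identical configurations are byte-identical.

## Problem sizes and runtime

The default simulation (20 genes / ~50 isoforms / 2,000 reads) is the
scale at which noise-free recovery is exact and each full pipeline run
takes well under a second; the test suite and the acceptance script each
complete in seconds. Exhaustive oracles (Fisher enumeration, O(n²)
distance pairs, union-find clustering) run at n ≤ a few hundred, where
exact arithmetic is cheap.

## Known limitations

* Recovery is evaluated against isoforms identified by (chain, TSS, polyA);
  isoform pairs engineered to be closer than the clustering resolution
  would merge, by design.
* The pipeline's intactness call is read-level and evidence-near-end
  based; it cannot distinguish a decay intermediate whose 5′ end happens to
  coincide with a genuine alternative TSS — no method relying on positional
  end evidence can.
* `exact_place` is exact string search: adequate for toy genomes, not a
  replacement for a spliced aligner on real data; real alignments enter
  through SAM/BAM.
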