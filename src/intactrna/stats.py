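"""Cross-species overlap statistics and the sperm-purity regression.

The overlap analysis asks whether genes producing intact sperm transcripts
in one species tend to have homologs doing the same in another, over the
universe of genes shared between the species.  Because the homolog map can
be one-to-many, the two directional overlap fractions need not agree.
Enrichment is assessed with a one-sided Fisher exact test computed in log
space, so p-values far below float underflow remain exact.

The purity regression asks how much of a bulk expression profile Y can be
explained by a linear combination of per-cluster consensus profiles X from
single-cell data: cells are normalized to unit total count, each cluster's
consensus is the gene-wise median, and Y is regressed on X by ordinary
least squares.  A high R^2 would indicate contamination by those cell
types; near zero indicates a pure sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)

_LOG10 = np.log(10.0)


class HomologMap:
    """Unique (species-A gene, species-B gene) pairs; one-to-many allowed."""

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        self.pairs: list[tuple[str, str]] = sorted(set(pairs))
        self.a_to_b: dict[str, set[str]] = {}
        self.b_to_a: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self.a_to_b.setdefault(a, set()).add(b)
            self.b_to_a.setdefault(b, set()).add(a)

    @property
    def universe_a(self) -> set[str]:
        return set(self.a_to_b)

    @property
    def universe_b(self) -> set[str]:
        return set(self.b_to_a)

    @property
    def n_universe(self) -> int:
        """Shared-gene universe size, counted at the species-A gene level."""
        return len(self.a_to_b)

    @classmethod
    def from_tsv(cls, path: str) -> "HomologMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass(frozen=True)
class OverlapResult:
    a: int  # genes with intact transcripts in both species (A-gene level)
    b: int  # species-A only
    c: int  # species-B only (A genes whose homolog is in the B set)
    d: int  # neither
    fraction_a: float
    fraction_b: float
    log10_p: float

    @property
    def n_universe(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_log(a: int, b: int, c: int, d: int) -> float:
    """log10 of the one-sided (enrichment) Fisher exact p for a 2x2 table.

    The p-value is the upper hypergeometric tail P[X >= a] with population
    a+b+c+d, a+b successes and a+c draws, computed via log-factorials so it
    stays exact down to (and far below) 1e-300.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entry {name} must be a non-negative integer, got {v}")
    n = a + b + c + d
    k_row = a + b
    k_col = a + c
    lo = max(0, k_row + k_col - n)
    hi = min(k_row, k_col)

    def log_pmf(x: int) -> float:
        return (
            gammaln(k_row + 1)
            - gammaln(x + 1)
            - gammaln(k_row - x + 1)
            + gammaln(n - k_row + 1)
            - gammaln(k_col - x + 1)
            - gammaln(n - k_row - (k_col - x) + 1)
            - (gammaln(n + 1) - gammaln(k_col + 1) - gammaln(n - k_col + 1))
        )

    xs = [x for x in range(max(lo, a), hi + 1)]
    if not xs:
        return 0.0  # P[X >= a] with empty tail support above a means a <= lo: p = 1
    logp = logsumexp([log_pmf(x) for x in xs])
    return float(min(logp, 0.0) / _LOG10)


def spirna_overlap(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    homologs: HomologMap,
) -> OverlapResult:
    """Directional overlap of two species' intact-transcript gene sets.

    A species-A gene overlaps iff ANY of its homologs lies in the species-B
    set (and symmetrically); this is why the two fractions can differ under
    one-to-many homology.  The 2x2 enrichment table is built at the
    species-A gene level.
    """
    if homologs.n_universe == 0:
        raise ValueError("empty homolog universe")
    set_a = set(genes_a) & homologs.universe_a
    set_b = set(genes_b) & homologs.universe_b

    a_hits = {g for g in set_a if homologs.a_to_b[g] & set_b}
    b_hits = {g for g in set_b if homologs.b_to_a[g] & set_a}
    fraction_a = len(a_hits) / len(set_a) if set_a else 0.0
    fraction_b = len(b_hits) / len(set_b) if set_b else 0.0

    a = len(a_hits)
    b_only = len(set_a) - a
    c = sum(1 for g in homologs.universe_a - set_a if homologs.a_to_b[g] & set_b)
    d = homologs.n_universe - a - b_only - c
    return OverlapResult(a, b_only, c, d, fraction_a, fraction_b, fisher_log(a, b_only, c, d))


def synthetic_homolog_universe(
    n_universe: int,
    n_a: int,
    n_b: int,
    overlap_a: int,
    overlap_b: int,
) -> tuple[set[str], set[str], HomologMap]:
    """Construct a synthetic homolog map realizing given overlap counts.

    Returns ``(genes_a, genes_b, homologs)`` such that the shared universe
    has ``n_universe`` species-A genes, ``n_a`` of them carry intact
    transcripts in species A, ``n_b`` species-B genes carry them in B, and
    exactly ``overlap_a`` A genes / ``overlap_b`` B genes overlap through
    homology.  ``overlap_b > overlap_a`` is realized with one-to-many
    homolog edges.  Useful for demonstrating the directional overlap
    arithmetic on published summary counts.
    """
    if not (overlap_a <= n_a <= n_universe and overlap_a <= overlap_b <= n_b):
        raise ValueError("infeasible overlap counts")
    extra = overlap_b - overlap_a
    if extra > overlap_a:
        raise ValueError("overlap_b - overlap_a exceeds available one-to-many sources")
    pairs = [(f"a{i}", f"b{i}") for i in range(n_universe)]
    pairs += [(f"a{i}", f"bx{i}") for i in range(extra)]
    genes_a = {f"a{i}" for i in range(n_a)}
    # covered B genes: homologs of the overlapping A genes (+ one-to-many
    # extras); uncovered B genes pair with non-intact A genes
    genes_b = {f"b{i}" for i in range(overlap_a)}
    genes_b |= {f"bx{i}" for i in range(extra)}
    genes_b |= {f"b{n_a + i}" for i in range(n_b - overlap_b)}
    return genes_a, genes_b, HomologMap(pairs)


@dataclass
class PurityRegressionResult:
    coefficients: pd.Series  # one per cluster (plus 'intercept' when fitted)
    r_squared: float
    n_genes: int
    degenerate: bool


def consensus_profiles(
    sc_counts: pd.DataFrame, cluster_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-cluster consensus profiles from a cells x genes count matrix.

    Each cell's counts are normalized to sum to one, then the gene-wise
    median is taken within each cluster.  Returns genes x clusters.
    """
    labels = pd.Series(list(cluster_labels), index=sc_counts.index)
    totals = sc_counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        log.warning("dropping %d empty cells", int((~keep).sum()))
    norm = sc_counts.loc[keep].div(totals[keep], axis=0)
    return norm.groupby(labels[keep]).median().T


def purity_regression(
    sc_counts: pd.DataFrame,
    cluster_labels: Sequence[str],
    bulk_profile: pd.Series,
    intercept: bool = True,
) -> PurityRegressionResult:
    """OLS of a bulk profile on single-cell cluster consensus profiles.

    Genes are restricted to those present in both, nonzero in the bulk
    profile and in every cluster column.  Reports per-cluster coefficients
    and R^2 (about the mean of Y when an intercept is fitted, uncentered
    otherwise); rank-deficient design matrices are flagged.
    """
    import statsmodels.api as sm

    x = consensus_profiles(sc_counts, cluster_labels)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    common = x.index.intersection(bulk_profile.index)
    x = x.loc[common]
    y = bulk_profile.loc[common].astype(float)
    mask = (y != 0) & (x != 0).all(axis=1)
    x, y = x.loc[mask], y.loc[mask]
    if len(y) < 2:
        raise ValueError("fewer than 2 common nonzero genes after trimming")

    design = sm.add_constant(x.to_numpy(), has_constant="add") if intercept else x.to_numpy()
    degenerate = bool(np.linalg.matrix_rank(design) < design.shape[1])
    fit = sm.OLS(y.to_numpy(), design).fit()
    names = (["intercept"] if intercept else []) + list(x.columns)
    coeffs = pd.Series(fit.params, index=names)
    return PurityRegressionResult(coeffs, float(fit.rsquared), len(y), degenerate)
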