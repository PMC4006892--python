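"""Rank-order gene-set enrichment via minimum-hypergeometric order statistics.

The probe-level significance ranking (q ascending, rank 1 = most significant)
is collapsed to one probe per gene — the best-ranked probe wins — giving a
ranked gene list with consecutive ranks 1..N. A gene set with n members at
ranks r_1 < r_2 < ... < r_n in that list is scored by the tail probabilities

    p_k = P(at least k of n ranks drawn uniformly without replacement
            from {1..N} fall within the top r_k positions),

i.e. the upper tail of a hypergeometric count (equivalently, the tail of the
k-th order statistic of the drawn ranks). The set's raw p-value is
min_k p_k — the minimum-hypergeometric statistic — which is sensitive to
overrepresentation at the top of the list and, unlike a Kolmogorov-Smirnov
scan, blind to depletion. The n tails are strongly dependent, so no
within-set multiple-testing adjustment is applied; across sets, a Bonferroni
adjustment over the number of testable sets is applied and sets are reported
at adjusted p <= alpha (default 0.01).

Because min_k p_k is a minimum of dependent tail probabilities it is NOT
uniform under the null; only the Bonferroni-adjusted value is used for
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, fsum, lgamma

import numpy as np
import pandas as pd

from .containers import GeneSet
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes with consecutive ranks 1..N; rank 1 = most significant."""

    ranks: pd.Series  # gene -> rank

    def __post_init__(self) -> None:
        n = len(self.ranks)
        if self.ranks.index.has_duplicates:
            raise InputError("ranked gene list contains duplicate genes")
        if n and sorted(self.ranks) != list(range(1, n + 1)):
            raise InputError("ranks must be a permutation of 1..N")

    @property
    def n_genes(self) -> int:
        return len(self.ranks)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ranks.index


@dataclass
class EnrichmentResult:
    """Per-set enrichment outcome."""

    name: str
    n: int  # effective set size (members present in the ranked list)
    member_ranks: tuple[int, ...]
    pk_values: tuple[float, ...]
    k_star: int  # smallest k attaining the minimum
    p_raw: float
    p_adjusted: float | None = None
    reported: bool | None = None
    testable: bool = True


def collapse_probes(de_table: pd.DataFrame, gene_col: str = "gene") -> RankedGeneList:
    """Collapse a q-sorted probe table to a ranked gene list.

    Whenever several probes represent the same gene, only the best-ranked
    (most significant) probe is kept; surviving genes are re-ranked
    consecutively 1..N. Probes with a missing gene annotation are dropped
    with a logged count.
    """
    genes = de_table[gene_col]
    missing = genes.isna() | (genes.astype(str).str.strip() == "")
    if missing.any():
        logger.warning("dropping %d probe(s) with no gene annotation", int(missing.sum()))
    kept = genes[~missing].astype(str)
    first = kept[~kept.duplicated(keep="first")]
    ranks = pd.Series(np.arange(1, len(first) + 1), index=first.to_numpy(), name="rank")
    return RankedGeneList(ranks=ranks)


def _log_comb(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def order_statistic_tail(N: int, n: int, k: int, r: int, variant: str = "top") -> float:
    """Tail probability of the k-th order statistic of n ranks drawn
    uniformly without replacement from {1..N}.

    With ``variant="top"`` (default) this is P(X >= k) where X counts draws
    falling in the top r positions — the hypergeometric upper tail used to
    detect overrepresentation at the top of the list. ``variant="literal"``
    instead scores the bottom of the list: P(at least k draws land in
    positions {r..N}).

    Computed in log space via log-gamma with compensated summation; the
    result lies in (0, 1].
    """
    if not (1 <= k <= n <= N):
        raise InputError(f"require 1 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not 1 <= r <= N:
        raise InputError(f"rank r must lie in [1, N], got r={r}, N={N}")
    if variant == "literal":
        r = N - r + 1  # successes are the positions {r..N}
    elif variant != "top":
        raise InputError(f"unknown variant {variant!r}")
    log_denom = _log_comb(N, n)
    j_lo = max(k, n - (N - r))  # need n - j draws available outside the top r
    terms = [
        exp(_log_comb(r, j) + _log_comb(N - r, n - j) - log_denom)
        for j in range(j_lo, min(n, r) + 1)
    ]
    p = fsum(terms)
    return min(1.0, max(p, 5e-324))


def gene_set_pvalue(ranked: RankedGeneList, gene_set: GeneSet, variant: str = "top") -> EnrichmentResult:
    """Score one gene set against the ranked list.

    p_k is evaluated at each member rank r_k (k = 1..n, ranks ascending);
    the raw set p-value is min_k p_k with ties in k broken toward the
    smallest k. A set with no member in the ranked list is returned flagged
    not testable.
    """
    member_ranks = tuple(sorted(int(ranked.ranks[g]) for g in gene_set.members if g in ranked))
    n = len(member_ranks)
    if n == 0:
        return EnrichmentResult(
            name=gene_set.name, n=0, member_ranks=(), pk_values=(),
            k_star=0, p_raw=1.0, testable=False,
        )
    N = ranked.n_genes
    pk = tuple(
        order_statistic_tail(N, n, k, r, variant=variant)
        for k, r in enumerate(member_ranks, start=1)
    )
    k_star = int(np.argmin(pk)) + 1  # np.argmin returns the first minimum
    return EnrichmentResult(
        name=gene_set.name, n=n, member_ranks=member_ranks, pk_values=pk,
        k_star=k_star, p_raw=pk[k_star - 1],
    )


def enrich_collection(
    ranked: RankedGeneList,
    sets: list[GeneSet],
    alpha: float = 0.01,
    variant: str = "top",
) -> list[EnrichmentResult]:
    """Score a collection of gene sets with Bonferroni adjustment.

    The Bonferroni factor m counts only testable sets (non-empty
    intersection with the ranked list). Results are sorted by
    (p_adjusted, name); ``reported`` marks sets with adjusted p <= alpha.
    """
    results = [gene_set_pvalue(ranked, gs, variant=variant) for gs in sets]
    testable = [res for res in results if res.testable]
    if not testable:
        raise InputError("no gene set intersects the ranked gene list")
    m = len(testable)
    logger.info("testing %d gene set(s) (%d supplied)", m, len(results))
    for res in testable:
        res.p_adjusted = min(1.0, res.p_raw * m)
        res.reported = res.p_adjusted <= alpha
    testable.sort(key=lambda res: (res.p_adjusted, res.name))
    untestable = sorted((r for r in results if not r.testable), key=lambda r: r.name)
    return testable + untestable


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set)."""
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "n": [r.n for r in results],
            "k_star": [r.k_star for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [np.nan if r.p_adjusted is None else r.p_adjusted for r in results],
            "reported": [bool(r.reported) for r in results],
            "testable": [r.testable for r in results],
        }
    ).set_index("set")
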