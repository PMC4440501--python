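"""GO term enrichment of DE gene sets by one-sided Fisher's exact test.

For each term the 2x2 table (DE vs not, annotated vs not) is summarised by the
upper hypergeometric tail P(X >= k), i.e. the one-sided Fisher enrichment
p-value.  The test universe is the *annotated* background: proteins without
any GO annotation are excluded from N.  Significance follows the permissive
raw p < 0.05 convention; BH-adjusted values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import GOAnnotation, go_term_sets

__all__ = ["EnrichmentResult", "fisher_enrichment", "summarize_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's contingency summary against an annotated background."""

    term_id: str
    term_name: str
    k: int  # DE genes annotated with the term
    K: int  # background genes annotated with the term
    n: int  # DE genes in the annotated universe
    N: int  # annotated background size
    pvalue: float
    bh_fdr: float = float("nan")

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent contingency counts for {self.term_id}: "
                f"k={self.k}, K={self.K}, n={self.n}, N={self.N}"
            )


def fisher_enrichment(
    de_proteins: Iterable[str],
    background_proteins: Iterable[str],
    go_map: Sequence[GOAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided enrichment test for every term annotating the background.

    ``de_proteins`` must be a subset of ``background_proteins``; both are
    restricted to proteins carrying at least one annotation before the
    universe sizes are computed.  Returns results for every term with K >= 1,
    sorted by p-value then term id, with a BH column over that term family.
    """
    de = set(de_proteins)
    bg = set(background_proteins)
    if not de <= bg:
        raise ValueError(
            f"DE set is not a subset of the background: "
            f"{sorted(de - bg)[:5]} ..."
        )
    term_sets = go_term_sets(go_map)
    names = {a.term_id: a.term_name for a in go_map}
    bg = {p for p in bg if term_sets.get(p)}
    de = de & bg
    N, n = len(bg), len(de)

    by_term: dict[str, set[str]] = {}
    for p in bg:
        for t in term_sets[p]:
            by_term.setdefault(t, set()).add(p)

    results = []
    for term_id in sorted(by_term):
        annotated = by_term[term_id]
        K = len(annotated)
        k = len(annotated & de)
        # upper tail P(X >= k) of Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if N else 1.0
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(term_id, names.get(term_id, ""), k, K, n, N, p)
        )
    fdrs = bh_adjust([r.pvalue for r in results])
    results = [
        EnrichmentResult(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.pvalue, f)
        for r, f in zip(results, fdrs)
    ]
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def summarize_enrichment(
    results_by_cell: Mapping[tuple, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
    parents: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Long-format comparative table of significant terms per analysis cell.

    ``results_by_cell`` maps a (species, time_point, direction) tuple to that
    cell's enrichment results.  A term is dropped from a cell when a child
    term (per the optional child -> parent table) is also significant in the
    same cell, keeping only the most specific significant terms; without a
    parent table all significant terms are retained.
    """
    rows = []
    for cell, results in results_by_cell.items():
        species, time_point, direction = cell
        sig = {r.term_id: r for r in results if r.pvalue < alpha}
        keep = set(sig)
        if parents:
            has_sig_child = {
                parents[c] for c in sig if c in parents and parents[c] in sig
            }
            keep -= has_sig_child
        for term_id in sorted(keep):
            r = sig[term_id]
            rows.append(
                {
                    "species": species,
                    "time_point": time_point,
                    "direction": direction,
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "pvalue": r.pvalue,
                    "bh_fdr": r.bh_fdr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "time_point", "direction", "term_id", "term_name",
            "k", "K", "n", "N", "pvalue", "bh_fdr",
        ],
    )
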