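"""Over-representation analysis of gene sets across annotation categories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom

from .dataio import AnnotationMap
from .discovery import fdr_qvalues
from .errors import ValidationError

MODE_FISHER = "fisher"
MODE_EASE = "ease"


@dataclass
class EnrichmentRow:
    term_id: str
    k: int  # selected genes in term
    K: int  # universe genes in term
    n: int  # selected genes total
    N: int  # universe genes total
    odds_ratio: float
    p_value: float
    q_value: float | None
    mode: str

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError("inconsistent 2x2 table: k out of range")
        if self.N < max(self.K, self.n):
            raise ValidationError("inconsistent 2x2 table: N too small")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_overrepresentation(
    selected: Iterable[str],
    universe: Iterable[str],
    ann: AnnotationMap,
    mode: str = MODE_FISHER,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[EnrichmentRow]:
    """One-sided exact over-representation test per annotation term.

    For each term the 2x2 table (in-term vs out-of-term, selected vs not)
    gets an upper-tail hypergeometric p-value; ``mode='ease'`` recomputes it
    after removing one selected in-term gene (k -> max(k-1, 0)), the
    conservative jackknife variant.  Universe genes without annotation count
    toward the out-of-term margin.  BH adjustment across terms; rows sorted
    by (p, term).
    """
    if mode not in (MODE_FISHER, MODE_EASE):
        raise ValidationError(f"unknown enrichment mode {mode!r}")
    sel = set(selected)
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    extra = sel - uni
    if extra:
        raise ValidationError(f"selected genes not in universe: {sorted(extra)[:5]}")

    gene_terms = ann.gene_terms()
    term_members: dict[str, set[str]] = {}
    for gene in uni:
        for term in gene_terms.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)

    N, n = len(uni), len(sel)
    rows: list[EnrichmentRow] = []
    for term, members in term_members.items():
        K = len(members)
        k = len(members & sel)
        k_eff = max(k - 1, 0) if mode == MODE_EASE else k
        if k == 0:
            p = 1.0
        else:
            p = hypergeom_tail(k_eff, N, K, n)
            if two_sided:
                p = min(1.0, 2.0 * min(p, 1.0 - p + _pmf(k_eff, N, K, n)))
        rows.append(
            EnrichmentRow(
                term_id=term,
                k=k,
                K=K,
                n=n,
                N=N,
                odds_ratio=_odds_ratio(k, K, n, N),
                p_value=p,
                q_value=None,
                mode=mode,
            )
        )
    if rows:
        q = fdr_qvalues([r.p_value for r in rows], method="bh")
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def _pmf(k: int, N: int, K: int, n: int) -> float:
    return float(hypergeom.pmf(k, N, K, n))


def category_coverage_report(
    selected: Iterable[str], ann: AnnotationMap
) -> dict[str, list[str]]:
    """Every term touched by >= 1 selected gene, with its sorted member list.

    Descriptive companion output for the case where no term passes the
    significance threshold.
    """
    sel = set(selected)
    gene_terms = ann.gene_terms()
    report: dict[str, set[str]] = {}
    for gene in sel:
        for term in gene_terms.get(gene, ()):
            report.setdefault(term, set()).add(gene)
    return {term: sorted(genes) for term, genes in sorted(report.items())}


def write_enrichment_table(rows: list[EnrichmentRow], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("term_id\tk\tK\tn\tN\todds_ratio\tp\tq\tmode\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.10g}\t{r.q_value:.10g}\t{r.mode}\n"
            )
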