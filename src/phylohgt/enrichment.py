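"""Hypergeometric over-representation of functional terms with BH FDR.

For a study set of n genes drawn from a background of N annotated genes, a
term annotating K background genes and k study genes has upper-tail p-value

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

computed in log space for stability.  Benjamini-Hochberg step-up q-values
control the false discovery rate across terms.  Both primitives are authored
here from first principles; library routines appear only as independent
cross-checks in the test suite.

The background universe is whatever annotated gene complement the caller
supplies; reports always carry N so results stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class AnnotationUniverse:
    background_genes: set[str]
    term_to_genes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            stray = genes - self.background_genes
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def size(self) -> int:
        return len(self.background_genes)


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float = float("nan")


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return float("-inf")
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments k={k} n={n} K={K} N={N}")
    hi = min(n, K)
    if k > hi:
        raise ValueError(f"k={k} exceeds min(n, K)={hi}")
    if k <= max(0, n + K - N):
        return 1.0
    denom = _log_comb(N, n)
    logs = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - denom for i in range(k, hi + 1)
    ]
    m = max(logs)
    total = m + log(sum(exp(v - m) for v in logs))
    return min(exp(total), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def enrich(
    study_set: Iterable[str],
    universe: AnnotationUniverse,
    min_term_size: int = 5,
) -> list[EnrichmentResult]:
    """One upper-tail test per term with K >= min_term_size, BH-adjusted.

    Study genes missing from the background are an error: the universe choice
    must be explicit, not patched silently.
    """
    study = set(study_set)
    stray = study - universe.background_genes
    if stray:
        raise ValueError(
            f"study genes not in the background universe: {sorted(stray)[:5]}"
        )
    n = len(study)
    N = universe.size
    results = []
    for term in sorted(universe.term_to_genes):
        genes = universe.term_to_genes[term]
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(genes & study)
        results.append(
            EnrichmentResult(term=term, k=k, n=n, K=K, N=N,
                             p_value=hypergeom_upper(k, n, K, N))
        )
    if not results or n == 0:
        return [] if n == 0 else results
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


def load_universe(path: str | Path, background: Optional[set[str]] = None) -> AnnotationUniverse:
    """Read a two-column gene_id/term_id TSV into an annotation universe.

    Without an explicit background, the universe is the set of annotated
    genes in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValueError("annotation file needs columns gene_id, term_id")
    term_to_genes: dict[str, set[str]] = {}
    for term, sub in df.groupby("term_id"):
        term_to_genes[str(term)] = set(sub["gene_id"].astype(str))
    bg = background if background is not None else set(df["gene_id"].astype(str))
    return AnnotationUniverse(background_genes=bg, term_to_genes=term_to_genes)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.k, r.n, r.K, r.N, r.p_value, r.q_value) for r in results],
        columns=["term", "k", "n", "K", "N", "p", "q"],
    )
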