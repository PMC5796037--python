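"""Over-representation analysis of gene lists against GMT gene sets.

The statistic is the hypergeometric upper tail P(X >= k) for k hits in a
list of n genes against a set of K members in a background of N, with an
optional EASE variant (the tail computed with one hit removed, the more
conservative score popularised by annotation servers).  Benjamini-
Hochberg q-values are attached across the batch of terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int          # hits in the list
    K: int          # set size within the background
    n: int          # list size
    N: int          # background size
    p_value: float
    q_value: float
    ease_p: float | None = None


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated in log space."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ConfigError(
            f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}"
        )
    if k == 0:
        return 1.0
    # survival function at k-1 = P(X >= k); scipy evaluates via gammaln
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_list,
    gene_sets: GeneSetCollection,
    background=None,
    use_ease: bool = False,
) -> list[EnrichmentResult]:
    """One hypergeometric test per term with >= 1 hit, sorted by p.

    The background defaults to the union of all set members.  List genes
    outside the background are dropped with a warning.  ``use_ease``
    additionally reports the EASE score, the tail with (k-1) hits, which
    is 1 whenever k = 1.
    """
    if background is None:
        background = gene_sets.background()
    bg = set(background)
    if not bg:
        raise ConfigError("empty enrichment background")

    genes = list(dict.fromkeys(gene_list))
    inside = [g for g in genes if g in bg]
    if len(inside) < len(genes):
        logger.warning(
            "enrich: dropped %d gene(s) outside the background",
            len(genes) - len(inside),
        )
    n, N = len(inside), len(bg)
    query = set(inside)

    rows = []
    for term, (name, members) in gene_sets.sets.items():
        mset = set(members) & bg
        k = len(mset & query)
        if k == 0:
            continue
        K = len(mset)
        p = hypergeom_tail(k, K, n, N)
        ease = hypergeom_tail(max(k - 1, 0), K, n, N) if use_ease else None
        rows.append((term, name, k, K, p, ease))

    q = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(term, name, k, K, n, N, p, float(qv), ease)
        for (term, name, k, K, p, ease), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_to_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp\tq\tease_p\n")
        for r in results:
            ease = "NA" if r.ease_p is None else f"{r.ease_p:.6g}"
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{ease}\n"
            )
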