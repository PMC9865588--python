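"""Over-representation analysis (ORA) with Benjamini–Hochberg FDR.

For a query of n candidate genes drawn from a background universe of N
genes, a gene set with K members overlapping the query in k genes is
scored with the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n),

and the per-collection p-values are adjusted with the BH step-up
procedure q_i = min_{j >= i} p_(j) * m / j (m = number of sets tested).
A set is significant when q < 0.05 (configurable).  An optional
human->mouse symbol mapping supports Mammalian-Phenotype-style
collections defined on mouse symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor, log10

import numpy as np
from scipy.stats import hypergeom

from .models import GeneList, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraConfig:
    min_set_size: int = 5
    max_set_size: int = 2000
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError(f"q_threshold must be in (0, 1), got {self.q_threshold}")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size exceeds max_set_size")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    K: int            # reference-set size
    k: int            # overlap with the query
    p: float          # hypergeometric upper tail
    q: float          # BH-adjusted
    significant: bool


@dataclass(frozen=True)
class OraReport:
    results: tuple[EnrichmentResult, ...]
    m: int              # number of sets actually tested (BH denominator)
    n_query: int        # query size after background restriction
    n_background: int
    q_threshold: float


def map_to_mouse(genes: GeneList, mapping: dict[str, str]) -> tuple[GeneList, list[str]]:
    """Translate human symbols through an ortholog mapping.

    Returns the deduplicated mapped list plus the sorted unmapped symbols
    (several human symbols mapping to one mouse symbol collapse to one).
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in sorted(genes.genes):
        if g in mapping:
            mapped.add(mapping[g])
        else:
            unmapped.append(g)
    if unmapped:
        logger.info("%d of %d symbols unmapped: %s", len(unmapped), len(genes), unmapped)
    return GeneList(name=f"{genes.name}_mouse", genes=frozenset(mapped)), unmapped


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters: k overlap, K set size, n query size, N background size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _hypergeom_upper_vec(k: np.ndarray, K: np.ndarray, n: int, N: int) -> np.ndarray:
    p = hypergeom.sf(k - 1, N, K, n)
    return np.where(k == 0, 1.0, p)


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    ``m`` defaults to ``len(pvalues)``; a larger ``m`` supports adjusting
    a top-hit subset against the full number of tests performed.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m={m} smaller than the number of p-values ({n})")
    if n == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


def _rounding_interval(x: float, sig_figs: int) -> tuple[float, float]:
    ulp = 10.0 ** (floor(log10(abs(x))) - (sig_figs - 1))
    return x - ulp / 2, x + ulp / 2


def find_consistent_m(
    pvalues, qvalues, sig_figs: int = 3, m_max: int = 10000
) -> list[int]:
    """Integer test counts m consistent with printed (p, q) pairs.

    Published tables print p and q rounded to a few significant figures,
    so the m actually used is recoverable by search: m is *consistent*
    when, for every entry, the step-up q interval induced by the p
    rounding interval overlaps the printed q's own rounding interval.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues and qvalues must be equal-length 1-D arrays")
    order = np.argsort(p, kind="mergesort")
    p, q = p[order], q[order]
    p_lo, p_hi = zip(*(_rounding_interval(x, sig_figs) for x in p))
    q_lo, q_hi = zip(*(_rounding_interval(x, sig_figs) for x in q))
    p_lo, p_hi = np.array(p_lo), np.array(p_hi)
    q_lo, q_hi = np.array(q_lo), np.array(q_hi)
    ranks = np.arange(1, p.size + 1)
    consistent = []
    for m in range(p.size, m_max + 1):
        lo = np.minimum.accumulate((p_lo * m / ranks)[::-1])[::-1]
        hi = np.minimum.accumulate((p_hi * m / ranks)[::-1])[::-1]
        if (np.minimum(lo, 1.0) <= q_hi).all() and (np.minimum(hi, 1.0) >= q_lo).all():
            consistent.append(m)
    return consistent


def run_ora(
    query: GeneList,
    collection: GeneSetCollection,
    config: OraConfig | None = None,
) -> OraReport:
    """Hypergeometric ORA of a gene list against a set collection.

    The query is restricted to the collection's background before
    testing; sets outside the configured size window are excluded, and
    the BH denominator m equals the number of sets actually tested.
    Results are sorted by p ascending, ties broken by set name.
    """
    config = config or OraConfig()
    background = collection.background
    restricted = query.genes & background
    if not restricted:
        raise ValueError(
            f"query {query.name!r} has no genes in the {len(background)}-gene background"
        )
    dropped = len(query.genes) - len(restricted)
    if dropped:
        logger.info("%d query genes outside the background were dropped", dropped)
    tested = sorted(
        name
        for name, members in collection.sets.items()
        if config.min_set_size <= len(members) <= config.max_set_size
    )
    m = len(tested)
    if m == 0:
        return OraReport((), 0, len(restricted), len(background), config.q_threshold)
    K = np.array([len(collection.sets[name]) for name in tested])
    k = np.array([len(collection.sets[name] & restricted) for name in tested])
    p = _hypergeom_upper_vec(k, K, len(restricted), len(background))
    q = bh_adjust(p, m)
    results = [
        EnrichmentResult(
            set_name=name,
            K=int(K[i]),
            k=int(k[i]),
            p=float(p[i]),
            q=float(q[i]),
            significant=bool(q[i] < config.q_threshold),
        )
        for i, name in enumerate(tested)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return OraReport(tuple(results), m, len(restricted), len(background), config.q_threshold)


def write_ora_table(report: OraReport, path) -> None:
    """TSV mirroring the published pathway table, with m and N in a header
    comment."""
    with open(path, "w") as fh:
        fh.write(
            f"# m={report.m} sets tested, N={report.n_background} background genes, "
            f"n={report.n_query} query genes, significance q<{report.q_threshold}\n"
        )
        fh.write("set_name\tn_reference_genes\tn_overlap\tp_value\tq_value\tsignificant\n")
        for r in report.results:
            fh.write(
                f"{r.set_name}\t{r.K}\t{r.k}\t{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
            )


def null_false_positive_rate(
    collection: GeneSetCollection,
    n_query: int,
    n_replicates: int = 1000,
    config: OraConfig | None = None,
    seed: int = 0,
) -> float:
    """Fraction of uniform-query replicates with >=1 significant set.

    Under the global null (query drawn uniformly from the background) the
    BH procedure controls this family-wise false-positive rate at the q
    threshold.  Fully vectorized across replicates.
    """
    config = config or OraConfig()
    rng = np.random.default_rng(seed)
    bg = sorted(collection.background)
    N = len(bg)
    if n_query > N:
        raise ValueError("query size exceeds background size")
    index = {g: i for i, g in enumerate(bg)}
    tested = sorted(
        name
        for name, members in collection.sets.items()
        if config.min_set_size <= len(members) <= config.max_set_size
    )
    m = len(tested)
    if m == 0:
        return 0.0
    M = np.zeros((m, N), dtype=np.float32)
    for i, name in enumerate(tested):
        M[i, [index[g] for g in collection.sets[name]]] = 1.0
    K = M.sum(axis=1).astype(int)

    X = np.zeros((N, n_replicates), dtype=np.float32)
    for r in range(n_replicates):
        X[rng.choice(N, size=n_query, replace=False), r] = 1.0
    k = np.rint(M @ X).astype(int)                       # (m, n_replicates)
    p = hypergeom.sf(k - 1, N, K[:, None], n_query)
    p = np.where(k == 0, 1.0, p)
    p_sorted = np.sort(p, axis=0)
    ranks = np.arange(1, m + 1)[:, None]
    q_min = (p_sorted * m / ranks).min(axis=0)           # min step-up q per replicate
    return float((q_min < config.q_threshold).mean())
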