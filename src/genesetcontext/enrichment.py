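"""Context enrichment among POI-selected samples.

Given N compendium samples of which K match the pattern of interest, and a
context with n_c samples of which k_c match, enrichment is tested with a
one-sided Fisher's exact test (hypergeometric upper tail, P(X >= k_c)), and
effect size is summarized by a pseudocounted fold change

    f_c = ((k_c + K/N) / (n_c + 1)) / (K/N)

i.e. the context's selection rate over the global selection rate, stabilized
for small contexts. Raw p-values from the C per-context tests are Bonferroni
corrected (p_adj = min(1, C * p)); contexts with p_adj < 0.05 and fold
change > 1.5 (defaults, strict) are reported, ranked by ascending adjusted
p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._errors import ValidationError
from .activity import ActivityMatrix
from .compendium import ExpressionCompendium
from .poi import POI, match_samples

logger = logging.getLogger(__name__)

__all__ = [
    "ContextEnrichmentResult",
    "EnrichmentReport",
    "fisher_enrichment_p",
    "poi_fold_change",
    "adjust_bonferroni",
    "run_enrichment",
    "write_ranking_table",
    "read_ranking_table",
    "estimate_unsupported_fraction",
]

RANKING_COLUMNS = ["context", "n_c", "k_c", "fold_change", "p_raw", "p_adj"]


@dataclass(frozen=True)
class ContextEnrichmentResult:
    """One context's 2x2 counts and enrichment statistics."""

    context: str
    n_c: int
    k_c: int
    fold_change: float
    p_raw: float
    p_adj: float


@dataclass
class EnrichmentReport:
    """Filtered, ranked results plus the complete unfiltered table."""

    reported: list[ContextEnrichmentResult]
    full: list[ContextEnrichmentResult]
    n_total: int
    n_selected: int
    n_contexts: int


def _check_counts(k_c: int, n_c: int, K: int, N: int) -> None:
    if not (0 <= n_c <= N and 0 <= K <= N):
        raise ValidationError(f"inconsistent counts: n_c={n_c}, K={K}, N={N}")
    if not (0 <= k_c <= min(n_c, K)):
        raise ValidationError(
            f"inconsistent counts: k_c={k_c} outside [0, min({n_c}, {K})]"
        )
    if n_c - k_c > N - K:
        raise ValidationError(
            f"inconsistent counts: {n_c - k_c} unselected context samples but "
            f"only {N - K} unselected samples in total"
        )


def fisher_enrichment_p(k_c: int, n_c: int, K: int, N: int) -> float:
    """One-sided (enrichment) Fisher's exact test p-value.

    Probability that a hypergeometric draw of n_c samples from N, of which K
    are selected, contains at least k_c selected samples.
    """
    _check_counts(k_c, n_c, K, N)
    # sf(k-1) = P(X >= k) for X ~ Hypergeom(N, K, n_c)
    return float(min(1.0, hypergeom.sf(k_c - 1, N, K, n_c)))


def poi_fold_change(k_c: int, n_c: int, K: int, N: int) -> float:
    """Pseudocounted ratio of context selection rate to global selection rate."""
    if K < 1:
        raise ValidationError("fold change undefined when no sample matches the POI")
    _check_counts(k_c, n_c, K, N)
    rate = K / N
    return ((k_c + rate) / (n_c + 1)) / rate


def adjust_bonferroni(p_values: list[float], n_tests: int) -> list[float]:
    """Bonferroni correction: p_adj = min(1, C * p) for C hypothesis tests."""
    if n_tests < len(p_values):
        raise ValidationError(
            f"n_tests={n_tests} smaller than the {len(p_values)} p-values given"
        )
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, n_tests * p))
    return out


def run_enrichment(
    comp: ExpressionCompendium,
    act: ActivityMatrix,
    poi: POI,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
) -> EnrichmentReport:
    """Test every annotated context for enrichment among POI-selected samples.

    All C distinct contexts are tested (C is also the Bonferroni factor).
    Contexts with p_adj < p_cutoff and fold_change > fc_cutoff (both strict)
    are reported, ranked by ascending p_adj, ties broken by descending fold
    change, then label. If the POI matches no sample, a warning is logged
    and an empty report returned (fold change is undefined at K=0).
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValidationError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    if fc_cutoff < 0:
        raise ValidationError(f"fc_cutoff must be >= 0, got {fc_cutoff}")
    if act.sample_ids != comp.sample_ids:
        raise ValidationError("activity matrix and compendium sample order differ")

    mask = np.asarray(match_samples(poi, act), dtype=bool)
    labels = comp.context_labels()
    contexts = sorted(set(labels))
    N = comp.n_samples
    K = int(mask.sum())
    if K == 0:
        logger.warning("POI matches no samples; returning empty enrichment report")
        return EnrichmentReport([], [], n_total=N, n_selected=0,
                                n_contexts=len(contexts))

    label_arr = np.asarray(labels)
    C = len(contexts)
    rows = []
    for ctx in contexts:
        in_ctx = label_arr == ctx
        n_c = int(in_ctx.sum())
        k_c = int((in_ctx & mask).sum())
        p = fisher_enrichment_p(k_c, n_c, K, N)
        rows.append((ctx, n_c, k_c, poi_fold_change(k_c, n_c, K, N), p))
    adj = adjust_bonferroni([r[4] for r in rows], C)
    full = [
        ContextEnrichmentResult(ctx, n_c, k_c, fc, p, pa)
        for (ctx, n_c, k_c, fc, p), pa in zip(rows, adj)
    ]
    full.sort(key=lambda r: (r.p_adj, -r.fold_change, r.context))
    reported = [
        r for r in full if r.p_adj < p_cutoff and r.fold_change > fc_cutoff
    ]
    logger.info(
        "enrichment: N=%d samples, K=%d selected, C=%d contexts, %d reported",
        N, K, C, len(reported),
    )
    return EnrichmentReport(reported, full, n_total=N, n_selected=K, n_contexts=C)


def write_ranking_table(results: list[ContextEnrichmentResult], path) -> None:
    """Write results as a 6-column TSV in the given (ranked) order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.context}\t{r.n_c}\t{r.k_c}\t"
                f"{r.fold_change:.8g}\t{r.p_raw:.8g}\t{r.p_adj:.8g}\n"
            )


def read_ranking_table(path) -> list[ContextEnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"context": str})
    if list(df.columns) != RANKING_COLUMNS:
        raise ValidationError(f"{path}: unexpected columns {list(df.columns)}")
    return [
        ContextEnrichmentResult(
            context=str(row.context), n_c=int(row.n_c), k_c=int(row.k_c),
            fold_change=float(row.fold_change), p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
        )
        for row in df.itertuples(index=False)
    ]


def estimate_unsupported_fraction(n_reported: int, n_supported: int) -> float:
    """Percentage of reported contexts without independent support.

    A conservative empirical false-discovery estimate: of ``n_reported``
    contexts called enriched, ``n_supported`` have independent (e.g.
    literature) support; the remainder, as a percentage, bounds the FDR
    from above (some unsupported calls may simply be unstudied).
    """
    if n_reported < 1:
        raise ValidationError("n_reported must be >= 1")
    if not 0 <= n_supported <= n_reported:
        raise ValidationError(
            f"n_supported={n_supported} outside [0, {n_reported}]"
        )
    return 100.0 * (n_reported - n_supported) / n_reported
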