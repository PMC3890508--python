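"""GO-term overrepresentation by the one-sided Fisher / hypergeometric test.

A study set of proteins is compared with a reference proteome: for each
term, the probability of observing at least the study count under
hypergeometric sampling (which equals the one-sided Fisher's exact test
on the 2x2 table).  No multiple-testing correction is applied by
default — with study sets of a handful of clusters against a whole
proteome the per-term counts are too small for correction to be
meaningful — but Bonferroni and Benjamini-Hochberg are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .simulate import GOAnnotationTable


@dataclass
class EnrichmentParams:
    alpha: float = 0.05
    correction: str = "none"  # none | bonferroni | bh

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("none", "bonferroni", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # term count in the study set
    n: int  # study set size
    K: int  # term count in the reference
    N: int  # reference size
    p_value: float
    significant: bool


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    *N* is the population size, *K* the number of annotated items in it,
    *n* the sample size and *k* the observed annotated count.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValueError(f"k={k} exceeds K={K}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy works in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(study_set, reference_set, annotations: GOAnnotationTable,
                 params: EnrichmentParams | None = None
                 ) -> list[EnrichmentResult]:
    """Test every reference term for overrepresentation in the study set.

    The term universe is the set of terms annotated at least once in the
    reference; results are sorted by p-value then term id.
    """
    params = params or EnrichmentParams()
    params.validate()
    study = set(study_set)
    reference = set(reference_set)
    if not study <= reference:
        raise ValueError("study set must be a subset of the reference set")
    if not study:
        warnings.warn("empty study set: no enrichment computed")
        return []

    term_ref: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for pid, term in annotations.rows:
        if pid in reference:
            term_ref[term] = term_ref.get(term, 0) + 1
            if pid in study:
                term_study[term] = term_study.get(term, 0) + 1

    N, n = len(reference), len(study)
    raw = []
    for term in sorted(term_ref):
        K = term_ref[term]
        k = term_study.get(term, 0)
        raw.append((term, k, K, hypergeom_tail(k, K, n, N)))

    pvals = [p for (_t, _k, _K, p) in raw]
    if params.correction == "none":
        flags = [p < params.alpha for p in pvals]
    else:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[params.correction]
        flags = list(multipletests(pvals, alpha=params.alpha,
                                   method=method)[0])

    results = [
        EnrichmentResult(term_id=t, k=k, n=n, K=K, N=N, p_value=p,
                         significant=bool(sig))
        for (t, k, K, p), sig in zip(raw, flags)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
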