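"""Hypergeometric over/under-representation engines.

Two urns are tested:

* genomic-feature representation of DMCs against the digest-capturable CpG
  background (two-sided by default, since both depletion and enrichment are
  of interest), with a Haldane-corrected log2 odds ratio as effect size;
* gene-set over-representation (ORA) of a query gene list against a domain
  of background genes (one-sided upper tail), with the enrichment ratio

      intersection_size / ((term_size / effective_domain_size) * query_size)

  as effect size, i.e. observed over expected overlap.

Both correct across tests with Benjamini–Hochberg; significance is FDR < 0.05.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


def _hypergeom_two_sided(k: int, N: int, K: int, n: int) -> float:
    """Doubling rule: 2 * min(P[X<=k], P[X>=k], 0.5)."""
    lower = hypergeom.cdf(k, N, K, n)
    upper = hypergeom.sf(k - 1, N, K, n)
    return float(min(1.0, 2.0 * min(lower, upper, 0.5)))


def log2_odds_ratio(k: int, n: int, K: int, N: int) -> float:
    """Haldane-corrected log2 odds ratio of feature membership among DMCs
    versus the rest of the background urn."""
    a = k + 0.5
    b = (n - k) + 0.5
    c = (K - k) + 0.5
    d = ((N - n) - (K - k)) + 0.5
    return math.log2((a / b) / (c / d))


def feature_representation(
    dmc_features: Mapping,
    background_features: Mapping,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Per-feature hypergeometric test of DMC counts against the background urn.

    ``dmc_features`` / ``background_features`` map feature label → count.
    The urn has N = total background CpGs with K per feature; n = total DMCs
    are drawn and k fall in the feature.
    """
    features = sorted(background_features, key=str)
    N = int(sum(background_features.values()))
    n = int(sum(dmc_features.get(f, 0) for f in features))
    unknown = set(dmc_features) - set(features)
    if unknown:
        raise ValueError(f"DMC features absent from background: {sorted(map(str, unknown))}")
    rows = []
    for f in features:
        K = int(background_features[f])
        k = int(dmc_features.get(f, 0))
        if k > K:
            raise ValueError(f"feature {f}: DMC count {k} exceeds background count {K}")
        if two_sided:
            p = _hypergeom_two_sided(k, N, K, n)
        else:
            p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "feature": str(f),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "log2_odds_ratio": log2_odds_ratio(k, n, K, N),
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def ora(
    query_genes: Iterable[str],
    genesets: GeneSetCollection,
    background_genes: Iterable[str],
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Gene-set over-representation: one-sided upper hypergeometric tail.

    Sets are intersected with the background before testing; sets with no
    member in the background are dropped.  The query must be a subset of the
    background.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]} ...")
    N = len(background)
    n = len(query)
    rows = []
    for set_id, (desc, members) in genesets:
        term = members & background
        if not term:
            continue
        K = len(term)
        k = len(term & query)
        expected = (K / N) * n
        rows.append(
            {
                "set_id": set_id,
                "description": desc,
                "intersection_size": k,
                "term_size": K,
                "effective_domain_size": N,
                "query_size": n,
                "enrichment_ratio": k / expected if expected > 0 else float("nan"),
                "pvalue": float(hypergeom.sf(k - 1, N, K, n)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_id", "description", "intersection_size", "term_size",
                "effective_domain_size", "query_size", "enrichment_ratio",
                "pvalue", "fdr", "significant",
            ]
        )
    out = pd.DataFrame(rows).sort_values("pvalue", kind="stable").reset_index(drop=True)
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def map_orthologs(
    genes: Iterable[str], mapping: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Translate gene ids through a source→target ortholog table.

    Many-to-one mappings collapse; output is deduplicated in first-seen
    order.  Returns (mapped, unmapped); unmapped genes are dropped and logged.
    """
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        if g in mapping:
            t = mapping[g]
            if t not in seen:
                seen.add(t)
                mapped.append(t)
        else:
            unmapped.append(g)
    if unmapped:
        log.info("map_orthologs: %d genes without orthologs dropped", len(unmapped))
    return mapped, unmapped
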