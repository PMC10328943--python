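"""Joining differential expression with differential methylation.

The observation unit is a (gene, DMC) pair: a differentially expressed gene
paired with each of its differentially methylated CpGs in a region of
interest (promoter or gene body), from the same pairwise comparison.  A gene
with several DMCs contributes several pairs; a gene-averaged mode is
available through :func:`aggregate_pairs_by_gene`.

Pairs are stratified into expression-change quantiles — eight for gene-body
pairs, four for promoter pairs by default — with boundaries computed over
the DISTINCT genes' log2FC (type-7 linear-interpolation quantiles), so genes
carrying many DMCs do not distort the boundaries.  Within each quantile a
Spearman correlation between log2FC and the methylation difference is
tested, with family-wise control at alpha/m (Bonferroni across the m
quantiles).  For n <= 9 pairs the permutation distribution of rho is
enumerated exactly; larger strata use the t approximation.

Separately, the deduplicated list of genes with both an expression change
and promoter/gene-body differential methylation is emitted as input for
over-representation analysis, without any quantile segmentation.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotate import AnnotationIndex

log = logging.getLogger(__name__)


def pair_deg_dmc(
    degs: pd.DataFrame,
    dmcs: pd.DataFrame,
    annotation_index: AnnotationIndex,
    region: str,
    body_includes_tail: bool = True,
) -> pd.DataFrame:
    """One row per (DEG, DMC-in-its-region) pair.

    ``degs`` must carry ``is_deg`` (gene_id index, from call_degs); ``dmcs``
    must carry ``status`` (from call_dmcs).  ``region`` is "promoter" or
    "gene_body".
    """
    if region not in ("promoter", "gene_body"):
        raise ValueError("region must be 'promoter' or 'gene_body'")
    deg_only = degs[degs["is_deg"]]
    dmc_only = dmcs[dmcs["status"].isin(["hyper", "hypo"])]
    rows = []
    for _, r in dmc_only.iterrows():
        reg, gene = annotation_index.assign_dmc_region(
            r["contig"], int(r["pos"]), body_includes_tail=body_includes_tail
        )
        if reg != region or gene is None or gene not in deg_only.index:
            continue
        d = deg_only.loc[gene]
        rows.append(
            {
                "gene_id": gene,
                "contig": r["contig"],
                "pos": int(r["pos"]),
                "region": region,
                "log2fc": float(d["log2fc"]),
                "pvalue_expr": float(d["pvalue"]),
                "delta_meth": float(r["delta"]),
                "pvalue_meth": float(r["pvalue"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "contig", "pos", "region", "log2fc", "pvalue_expr",
            "delta_meth", "pvalue_meth",
        ],
    )


def aggregate_pairs_by_gene(pairs: pd.DataFrame) -> pd.DataFrame:
    """Gene-mean alternative: average the methylation difference per gene."""
    if pairs.empty:
        return pairs.copy()
    agg = (
        pairs.groupby("gene_id", sort=True)
        .agg(
            region=("region", "first"),
            log2fc=("log2fc", "first"),
            pvalue_expr=("pvalue_expr", "first"),
            delta_meth=("delta_meth", "mean"),
            pvalue_meth=("pvalue_meth", "min"),
        )
        .reset_index()
    )
    return agg


def quantile_stratify(pairs: pd.DataFrame, m: int) -> pd.DataFrame:
    """Attach 1-based quantile indices from the distinct genes' log2FC.

    Boundaries are type-7 quantiles at i/m, i = 1..m−1; a pair whose gene sits
    exactly on a boundary goes to the lower quantile.
    """
    gene_lfc = pairs.drop_duplicates("gene_id")["log2fc"].to_numpy()
    if len(gene_lfc) < m:
        raise ValueError(
            f"only {len(gene_lfc)} distinct genes for m={m} quantiles; "
            "reduce the number of quantiles"
        )
    if np.ptp(gene_lfc) == 0:
        raise ValueError("all log2FC equal: quantile boundaries are degenerate")
    bounds = np.quantile(gene_lfc, np.arange(1, m) / m, method="linear")
    out = pairs.copy()
    # side="left": a value equal to a boundary is inserted before it -> lower quantile
    out["quantile_index"] = np.searchsorted(bounds, out["log2fc"].to_numpy(), side="left") + 1
    return out


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9)."""
    n = len(x)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = (rx - rx.mean()) / rx.std(ddof=0)
    ry = (ry - ry.mean()) / ry.std(ddof=0)
    obs = abs(float(np.mean(rx * ry)))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = np.abs((rx[perms] * ry[None, :]).mean(axis=1))
    return float(np.mean(rhos >= obs - 1e-12))


def spearman_by_quantile(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-quantile Spearman correlation of log2FC against delta_meth.

    Quantiles with fewer than 3 pairs are flagged (rho NaN).  The family-wise
    threshold is ``alpha / m`` over the m quantiles present in the input.
    """
    if "quantile_index" not in pairs.columns:
        raise ValueError("run quantile_stratify first")
    m = int(pairs["quantile_index"].max())
    bonferroni_alpha = alpha / m
    rows = []
    for q in range(1, m + 1):
        sub = pairs[pairs["quantile_index"] == q]
        n = len(sub)
        if n < 3:
            rows.append(
                {
                    "quantile_index": q, "n_pairs": n, "rho": np.nan,
                    "pvalue": np.nan, "bonferroni_alpha": bonferroni_alpha,
                    "significant": False,
                }
            )
            if n:
                log.info("quantile %d has %d pairs (<3): rho not computed", q, n)
            continue
        x = sub["log2fc"].to_numpy()
        y = sub["delta_meth"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p_t = spearmanr(x, y)
            p = _exact_spearman_p(x, y) if n <= 9 else float(p_t)
        rows.append(
            {
                "quantile_index": q, "n_pairs": n, "rho": rho, "pvalue": p,
                "bonferroni_alpha": bonferroni_alpha,
                "significant": bool(np.isfinite(p) and p < bonferroni_alpha),
            }
        )
    return pd.DataFrame(rows)


def spearman_overall(pairs: pd.DataFrame) -> tuple[float, float]:
    """Unstratified Spearman over all pairs (rho, p)."""
    if len(pairs) < 3:
        return (float("nan"), float("nan"))
    rho, p = spearmanr(pairs["log2fc"], pairs["delta_meth"])
    return float(rho), float(p)


def joint_change_genes(
    degs: pd.DataFrame,
    dmcs: pd.DataFrame,
    annotation_index: AnnotationIndex,
    body_includes_tail: bool = True,
) -> list[str]:
    """Genes that are DEGs and carry >= 1 promoter or gene-body DMC.

    The deduplicated, sorted union fed to over-representation analysis;
    DMCs assigned to neither region (e.g. distal intergenic) never qualify.
    """
    deg_set = set(degs[degs["is_deg"]].index)
    out: set[str] = set()
    for _, r in dmcs[dmcs["status"].isin(["hyper", "hypo"])].iterrows():
        reg, gene = annotation_index.assign_dmc_region(
            r["contig"], int(r["pos"]), body_includes_tail=body_includes_tail
        )
        if reg in ("promoter", "gene_body") and gene in deg_set:
            out.add(gene)
    return sorted(out)
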