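"""Stratified rank–rank hypergeometric overlap (RRHO) between two
differential-expression signatures.

Each gene carries a signed rank metric, −log10(p) × sign(log2FC).  The
comparison is threshold-free: over a grid of rank-threshold pairs (i, j) the
overlap between the top-i genes of one list and the top-j genes of the other
is scored with a hypergeometric tail P[overlap >= observed].

The stratified scheme keeps concordant and discordant signal separate: each
of the four quadrants (up-up, down-down, up-down, down-up) is computed over
only the genes whose metric signs match that quadrant in the respective
lists, so e.g. a self-comparison has empty discordant quadrants by
construction.  All pixels of all four quadrants are jointly corrected with
Benjamini–Yekutieli, and matrices store −log10 of the adjusted p.

Per quadrant, the reported gene list is the overlap set at the most
significant pixel (ties broken toward the smallest thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

QUADRANTS = ("up-up", "down-down", "up-down", "down-up")

P_FLOOR = 1e-300


def signed_rank_metric(pvalue: float, log2fc: float) -> float:
    """−log10(p) times the sign of the fold change; p floored at 1e-300."""
    if not (0 < pvalue <= 1 or math.isnan(pvalue)):
        raise ValueError(f"p-value {pvalue} outside (0, 1]")
    return -math.log10(max(pvalue, P_FLOOR)) * float(np.sign(log2fc))


def ranked_list(de_results: pd.DataFrame) -> pd.Series:
    """Signed rank metrics for a DE result frame (gene_id index)."""
    p = de_results["pvalue"].clip(lower=P_FLOOR)
    metric = -np.log10(p) * np.sign(de_results["log2fc"])
    return pd.Series(metric.to_numpy(), index=de_results.index, name="metric")


@dataclass
class RRHOMap:
    """One quadrant of the overlap map."""

    quadrant: str
    step: int
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    neg_log10_adj_p: np.ndarray  # shape (len(thresholds_a), len(thresholds_b))
    genes: list[str] = field(default_factory=list)  # overlap at the best pixel
    n_universe: int = 0

    @property
    def max_signal(self) -> float:
        return float(self.neg_log10_adj_p.max()) if self.neg_log10_adj_p.size else 0.0


def _quadrant_universe(list_a: pd.Series, list_b: pd.Series, sa: int, sb: int) -> pd.Index:
    in_a = np.sign(list_a) == sa
    in_b = np.sign(list_b) == sb
    return list_a.index[(in_a & in_b.reindex(list_a.index)).to_numpy()]


def _order(metrics: pd.Series, sign: int) -> pd.Index:
    """Most extreme first within a quadrant; ties broken by gene id."""
    df = pd.DataFrame({"m": metrics * sign})
    df["gene"] = df.index
    df = df.sort_values(["m", "gene"], ascending=[False, True], kind="stable")
    return pd.Index(df["gene"])


def rrho_map(list_a: pd.Series, list_b: pd.Series, step: int | None = None) -> dict[str, RRHOMap]:
    """Compute all four stratified quadrants with joint BY correction.

    ``list_a``/``list_b`` are signed metrics indexed by gene over an
    identical universe.  ``step`` defaults to ceil(sqrt(total universe)).
    """
    ua, ub = set(list_a.index), set(list_b.index)
    if ua != ub:
        offending = sorted((ua ^ ub))[:10]
        raise ValueError(f"gene universes differ, e.g. {offending}")
    if list_a.index.has_duplicates or list_b.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked list")
    if step is not None and step < 1:
        raise ValueError("step must be >= 1")
    default_step = max(1, math.ceil(math.sqrt(len(list_a))))

    quadrant_signs = {
        "up-up": (1, 1),
        "down-down": (-1, -1),
        "up-down": (1, -1),
        "down-up": (-1, 1),
    }
    maps: dict[str, RRHOMap] = {}
    pixel_ps: list[float] = []
    pixel_ref: list[tuple[str, int, int]] = []
    overlaps: dict[str, np.ndarray] = {}
    orders: dict[str, tuple[pd.Index, pd.Index]] = {}

    for quad, (sa, sb) in quadrant_signs.items():
        universe = _quadrant_universe(list_a, list_b, sa, sb)
        N = len(universe)
        q_step = step if step is not None else default_step
        thresholds = np.arange(q_step, N + 1, q_step, dtype=int)
        if N > 0 and (len(thresholds) == 0 or thresholds[-1] != N):
            thresholds = np.append(thresholds, N)
        order_a = _order(list_a.loc[universe], sa)
        order_b = _order(list_b.loc[universe], sb)
        orders[quad] = (order_a, order_b)

        rank_b = pd.Series(np.arange(1, N + 1), index=order_b)
        rb_in_a_order = rank_b.reindex(order_a).to_numpy() if N else np.array([])

        ta, tb = thresholds, thresholds
        k = np.zeros((len(ta), len(tb)), dtype=int)
        for ii, i in enumerate(ta):
            rb = rb_in_a_order[:i]
            k[ii] = np.searchsorted(np.sort(rb), tb, side="right")
        overlaps[quad] = k
        if k.size:
            pmat = hypergeom.sf(k - 1, N, ta[:, None], tb[None, :])
            pixel_ps.extend(pmat.ravel().tolist())
            pixel_ref.extend(
                (quad, ii, jj) for ii in range(len(ta)) for jj in range(len(tb))
            )
        maps[quad] = RRHOMap(
            quadrant=quad,
            step=q_step,
            thresholds_a=ta,
            thresholds_b=tb,
            neg_log10_adj_p=np.zeros((len(ta), len(tb))),
            n_universe=N,
        )

    if pixel_ps:
        adj = multipletests(pixel_ps, method="fdr_by")[1]
        for (quad, ii, jj), q in zip(pixel_ref, adj):
            maps[quad].neg_log10_adj_p[ii, jj] = -math.log10(max(q, P_FLOOR))

    for quad, m in maps.items():
        if m.neg_log10_adj_p.size == 0 or m.n_universe == 0:
            continue
        flat = m.neg_log10_adj_p
        best = np.unravel_index(int(np.argmax(flat)), flat.shape)
        i, j = int(m.thresholds_a[best[0]]), int(m.thresholds_b[best[1]])
        order_a, order_b = orders[quad]
        top_a = set(order_a[:i])
        m.genes = sorted(g for g in order_b[:j] if g in top_a)
    return maps


def quadrant_gene_counts(maps: dict[str, RRHOMap]) -> dict[str, int]:
    """Overlap size at the most significant pixel, per quadrant."""
    return {q: len(m.genes) for q, m in maps.items()}
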