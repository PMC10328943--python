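"""Per-CpG two-group beta-binomial Wald tests and DMC/DMR calling.

Methylated read counts at a CpG are modelled as beta-binomial: sample j of a
group contributes y_j ~ BetaBinomial(n_j, pi, phi) with between-sample
overdispersion phi, so Var(y_j) = n_j pi (1-pi) (1 + (n_j - 1) phi).  Group
methylation levels are coverage-weighted pooled proportions, phi is a
per-site method-of-moments estimate shrunk toward the genome-wide median
(prior weight 10), and the Wald statistic (pA − pB) / SE is referred to the
standard normal, two-sided.

A site is a DMC when p < 0.05 and the methylation difference is at least
15 percentage points in magnitude.  Sign convention matches differential
expression: in "A vs B", delta = mean(A) − mean(B), so hypermethylation
means higher methylation in the first-named group.

DMRs are greedy merges of consecutive tested CpGs (gap <= 100 bp) whose
significant sites share a direction, kept when they span >= 50 bp, contain
>= 3 CpGs and >= 50 % significant sites — the conventional region defaults
for this model family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import MethCountTable

log = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.15
P_THRESHOLD = 0.05


def _pivot(meth: MethCountTable, samples: list[str]):
    """Wide matrices (sites × samples) of methylated and total counts."""
    rec = meth.records[meth.records["sample_id"].isin(samples)]
    m = rec.pivot_table(index=["contig", "pos"], columns="sample_id",
                        values="n_meth", fill_value=0)
    u = rec.pivot_table(index=["contig", "pos"], columns="sample_id",
                        values="n_unmeth", fill_value=0)
    m, u = m.align(u, fill_value=0)
    m = m.reindex(columns=samples, fill_value=0)
    u = u.reindex(columns=samples, fill_value=0)
    return m.to_numpy(dtype=float), (m + u).to_numpy(dtype=float), m.index


def _group_stats(y: np.ndarray, n: np.ndarray, min_cov: int):
    """Pooled proportion, X² overdispersion pieces and dof per site, using
    only samples at or above the coverage floor."""
    use = n >= min_cov
    n_use = np.where(use, n, 0.0)
    y_use = np.where(use, y, 0.0)
    tot = n_use.sum(axis=1)
    m_samples = use.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, y_use.sum(axis=1) / tot, np.nan)
    pq = p * (1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.where(
            (pq[:, None] > 0) & use,
            (y_use - n_use * p[:, None]) ** 2 / (n_use * pq[:, None]),
            0.0,
        ).sum(axis=1)
    dof = np.where(pq > 0, np.maximum(n_use - 1, 0).sum(axis=1), 0.0)
    mm = np.where(pq > 0, m_samples, 0)
    return p, tot, n_use, m_samples, x2, dof, mm


def betabinom_wald(
    meth: MethCountTable,
    group_a: str,
    group_b: str,
    min_cov: int = 5,
    min_samples: int = 2,
    shrink_weight: float = 10.0,
    phi: float | None = None,
) -> pd.DataFrame:
    """Beta-binomial Wald test per CpG, group A vs group B.

    Sites where either group has fewer than ``min_samples`` samples with
    coverage >= ``min_cov`` are emitted untested (``tested=False``, p NaN).
    Pass ``phi`` to fix the overdispersion instead of estimating it (``phi=0``
    reduces the test to an unpooled two-proportion z-test).
    """
    sa = sorted(meth.samples_in_group(group_a))
    sb = sorted(meth.samples_in_group(group_b))
    if not sa or not sb:
        raise ValueError("both groups need samples")
    ya, na_all, idx = _pivot(meth, sa + sb)
    ya, yb = ya[:, : len(sa)], ya[:, len(sa):]
    na, nb = na_all[:, : len(sa)], na_all[:, len(sa):]

    pa, tot_a, na_use, ma, x2a, dof_a, mma = _group_stats(ya, na, min_cov)
    pb, tot_b, nb_use, mb, x2b, dof_b, mmb = _group_stats(yb, nb, min_cov)
    tested = (ma >= min_samples) & (mb >= min_samples)

    if phi is None:
        # E[X2_g] = (m_g - 1)(1 + (n - 1) phi): estimating the pooled
        # proportion removes one sample's worth of the FULL beta-binomial
        # variance, hence the (m-1)/m scaling of the dof in the denominator
        with np.errstate(divide="ignore", invalid="ignore"):
            den = np.where(mma > 0, dof_a * (mma - 1) / np.maximum(mma, 1), 0.0) + \
                  np.where(mmb > 0, dof_b * (mmb - 1) / np.maximum(mmb, 1), 0.0)
            sub = np.maximum(mma - 1, 0) + np.maximum(mmb - 1, 0)
            raw = np.where(den > 0, (x2a + x2b - sub) / den, np.nan)
        dof = den
        raw = np.clip(raw, 0.0, 1.0)
        ok = tested & np.isfinite(raw) & (dof > 0)
        phi_med = float(np.median(raw[ok])) if ok.any() else 0.0
        weight = np.where(ok, mma + mmb - 2, 0.0)
        phi_site = np.where(
            ok,
            (weight * np.nan_to_num(raw) + shrink_weight * phi_med)
            / (weight + shrink_weight),
            phi_med,
        )
    else:
        phi_site = np.full(len(idx), float(phi))

    def group_var(p_hat, n_use, tot, phi_vec):
        # continuity-correct only degenerate proportions so phi=0 matches the
        # plain z-test exactly on non-degenerate counts
        y_tot = p_hat * tot
        p_var = np.where(
            (p_hat <= 0) | (p_hat >= 1), (y_tot + 0.5) / (tot + 1.0), p_hat
        )
        pq = p_var * (1 - p_var)
        num = (n_use * pq[:, None] * (1 + (n_use - 1) * phi_vec[:, None])).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(tot > 0, num / tot**2, np.nan)

    va = group_var(pa, na_use, tot_a, phi_site)
    vb = group_var(pb, nb_use, tot_b, phi_site)
    delta = pa - pb
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, delta / se, 0.0)
    pvalue = np.where(delta == 0, 1.0, 2.0 * norm.sf(np.abs(wald)))
    pvalue = np.where(tested, pvalue, np.nan)

    out = pd.DataFrame(
        {
            "contig": idx.get_level_values("contig"),
            "pos": idx.get_level_values("pos"),
            "mean_a": pa,
            "mean_b": pb,
            "delta": delta,
            "phi": phi_site,
            "wald_stat": np.where(tested, wald, np.nan),
            "pvalue": pvalue,
            "tested": tested,
        }
    ).sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
    n_skip = int((~tested).sum())
    if n_skip:
        log.info("betabinom_wald: %d sites untestable at min_cov=%d min_samples=%d",
                 n_skip, min_cov, min_samples)
    return out


def call_dmcs(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
) -> pd.DataFrame:
    """Assign hyper / hypo / ns status.

    hyper: p < 0.05 and delta >= +0.15; hypo: p < 0.05 and delta <= −0.15
    (thresholds inclusive on delta, strict on p).
    """
    out = results.copy()
    sig = out["pvalue"] < p_threshold
    status = np.where(
        sig & (out["delta"] >= delta_threshold),
        "hyper",
        np.where(sig & (out["delta"] <= -delta_threshold), "hypo", "ns"),
    )
    status = np.where(out["tested"], status, "ns")
    out["status"] = status
    n_hyper = int((out["status"] == "hyper").sum())
    n_hypo = int((out["status"] == "hypo").sum())
    log.info("call_dmcs: %d hyper, %d hypo", n_hyper, n_hypo)
    return out


@dataclass(frozen=True)
class DMRResult:
    contig: str
    start: int
    end: int  # half-open; spans the last CpG's CG dinucleotide
    n_cpgs: int
    n_significant: int
    mean_delta: float
    direction: str


def call_dmrs(
    dmc_results: pd.DataFrame,
    min_len: int = 50,
    min_cg: int = 3,
    max_gap: int = 100,
    min_sig_frac: float = 0.5,
) -> pd.DataFrame:
    """Greedy merge of tested CpGs into differentially methylated regions.

    A run breaks at gaps > ``max_gap`` and whenever a significant site's
    direction conflicts with the run's established direction.  A region is
    kept iff its span >= ``min_len`` bp, it holds >= ``min_cg`` CpGs, and at
    least ``min_sig_frac`` of them are significant.
    """
    if "status" not in dmc_results.columns:
        raise ValueError("run call_dmcs first: 'status' column required")
    rows = []
    tested = dmc_results[dmc_results["tested"]].sort_values(["contig", "pos"])
    for contig, sub in tested.groupby("contig", sort=True):
        run: list[pd.Series] = []
        run_sign = 0

        def flush():
            if not run:
                return
            sig = [r for r in run if r["status"] != "ns"]
            if not sig:
                return
            start = int(run[0]["pos"])
            end = int(run[-1]["pos"]) + 2  # cover the CG dinucleotide
            n = len(run)
            if (end - start) >= min_len and n >= min_cg and len(sig) / n >= min_sig_frac:
                mean_delta = float(np.mean([r["delta"] for r in sig]))
                rows.append(
                    DMRResult(
                        contig, start, end, n, len(sig), mean_delta,
                        "hyper" if mean_delta >= 0 else "hypo",
                    )
                )

        for _, r in sub.iterrows():
            sign = {"hyper": 1, "hypo": -1}.get(r["status"], 0)
            if run and (r["pos"] - run[-1]["pos"] > max_gap or (sign and run_sign and sign != run_sign)):
                flush()
                run, run_sign = [], 0
            run.append(r)
            if sign:
                run_sign = sign
        flush()
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["contig", "start", "end", "n_cpgs", "n_significant", "mean_delta", "direction"],
    )
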