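"""End-to-end orchestration of the four-comparison analysis.

Stage order: filter/normalize → differential expression per comparison →
differential methylation (DMCs, DMRs) per comparison → in-silico digest
background → feature annotation → representation tests → RRHO of the two
Attacker comparisons → z-score/k-means clustering of the DEG union →
expression–methylation integration per comparison and region → ORA on DEG
sets and joint-change sets (when gene sets are provided).

Every output is a TSV/BED under the results directory; the resolved
configuration and seed are serialized alongside so a run can be reproduced
byte-identically.  Warnings (clamps, untestable sites, unmapped genes) are
counted and summarized in ``run.log``, never silent.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, de, digest, dm, enrichment, integrate, io, rrho

log = logging.getLogger(__name__)

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("Attacker", "Parental"),
    ("Attacker", "Father"),
    ("Parental", "Father"),
    ("Father", "Mother"),
)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All inputs and stage parameters, with the analysis defaults."""

    # input paths
    fasta: str = ""
    gtf: str = ""
    counts: str = ""
    groups: str = ""
    coverage_dir: str = ""
    gmt: str = ""
    ortholog_table: str = ""
    # design
    comparisons: list[list[str]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_COMPARISONS]
    )
    rrho_pair: list[list[str]] = field(
        default_factory=lambda: [["Attacker", "Parental"], ["Attacker", "Father"]]
    )
    excluded_samples: list[str] = field(default_factory=list)
    seed: int = 0
    # thresholds / parameters
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    delta_threshold: float = 0.15
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    min_cov: int = 5
    min_samples: int = 2
    promoter_up: int = 2000
    tts_down: int = 1000
    digest_motif: str = "CCGG"
    digest_flank: int = 100
    kmeans_k: int = 8
    quantiles_gene_body: int = 8
    quantiles_promoter: int = 4
    fdr_threshold: float = 0.05
    rrho_step: int | None = None
    dmr_min_len: int = 50
    dmr_min_cg: int = 3
    dmr_max_gap: int = 100
    dmr_min_sig_frac: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        errors = validate_config_dict(raw)
        if errors:
            raise ValueError("invalid config:\n" + "\n".join(errors))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def validate_config_dict(raw: dict) -> list[str]:
    """Schema check: unknown keys rejected, obvious type errors reported."""
    errors = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    for key in ("lfc_threshold", "p_threshold", "delta_threshold", "min_cpm"):
        if key in raw and not isinstance(raw[key], (int, float)):
            errors.append(f"{key} must be numeric")
    if "comparisons" in raw:
        for c in raw["comparisons"]:
            if not (isinstance(c, (list, tuple)) and len(c) == 2):
                errors.append(f"comparison {c!r} must be a pair of group labels")
    return errors


def validate_config(path: str | Path) -> list[str]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config_dict(raw)


def _cmp_tag(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the results directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = [
        f"methylink {__version__}",
        f"seed: {config.seed}",
    ]
    warn_counts: Counter = Counter()

    def stage(name: str):
        log.info("stage: %s", name)
        run_log.append(f"stage: {name}")

    try:
        stage("load inputs")
        genome = io.read_fasta(config.fasta)
        genes = io.read_gtf(config.gtf)
        group_of = io.read_group_table(config.groups)
        counts = io.read_counts(config.counts, group_of)
        if config.excluded_samples:
            counts = counts.drop_samples(config.excluded_samples)
            run_log.append(f"excluded samples: {config.excluded_samples}")
        meth_frames = []
        cov_dir = Path(config.coverage_dir)
        meth_samples = [s for s in group_of if s not in set(config.excluded_samples)]
        for s in meth_samples:
            path = cov_dir / f"{s}.cov"
            if not path.exists() and path.with_suffix(".cov.gz").exists():
                path = path.with_suffix(".cov.gz")
            if not path.exists():
                raise PipelineError(f"stage 'load inputs': missing coverage file for sample {s!r}: {path}")
            meth_frames.append(io.read_meth_coverage(path, s))
        from .types import MethCountTable

        meth = MethCountTable(pd.concat(meth_frames, ignore_index=True),
                              {s: group_of[s] for s in meth_samples})
        genesets = io.read_gmt(config.gmt) if config.gmt else None
        orthologs = io.read_ortholog_table(config.ortholog_table) if config.ortholog_table else None

        stage("filter and normalize")
        filtered = de.filter_genes(counts, config.min_cpm, config.min_fraction)
        factors = de.size_factors(filtered)
        dispersions = de.estimate_dispersions(filtered, factors)

        stage("differential expression")
        de_results: dict[tuple[str, str], pd.DataFrame] = {}
        for a, b in config.comparisons:
            res = de.nb_lrt(filtered, a, b, factors, dispersions)
            res = de.call_degs(res, config.lfc_threshold, config.p_threshold)
            de_results[(a, b)] = res
            _write(res, outdir / f"de_{_cmp_tag(a, b)}.tsv", index=True)
            run_log.append(f"DEGs {_cmp_tag(a, b)}: {int(res['is_deg'].sum())}")

        stage("differential methylation")
        dm_results: dict[tuple[str, str], pd.DataFrame] = {}
        for a, b in config.comparisons:
            res = dm.betabinom_wald(meth, a, b, config.min_cov, config.min_samples)
            res = dm.call_dmcs(res, config.p_threshold, config.delta_threshold)
            dm_results[(a, b)] = res
            _write(res, outdir / f"dmc_{_cmp_tag(a, b)}.tsv")
            dmrs = dm.call_dmrs(res, config.dmr_min_len, config.dmr_min_cg,
                                config.dmr_max_gap, config.dmr_min_sig_frac)
            _write(dmrs, outdir / f"dmr_{_cmp_tag(a, b)}.tsv")
            n_hyper = int((res["status"] == "hyper").sum())
            n_hypo = int((res["status"] == "hypo").sum())
            warn_counts["untestable_sites"] += int((~res["tested"]).sum())
            run_log.append(
                f"DMCs {_cmp_tag(a, b)}: {n_hyper} hyper, {n_hypo} hypo; DMRs: {len(dmrs)}"
            )

        stage("digest background")
        background = digest.digest_genome(genome, config.digest_motif,
                                          flank=config.digest_flank)
        io.write_bed(
            [(c, p, p + 2) for c, p in background.sorted_positions()],
            outdir / "background_cpgs.bed",
        )
        run_log.append(f"capturable background CpGs: {len(background)}")

        stage("feature annotation")
        contig_lengths = {g.contig_name: len(g) for g in genome}
        index = annotate.build_index(genes, config.promoter_up, config.tts_down,
                                     contig_lengths=contig_lengths)
        bg_features = digest.background_feature_distribution(background, index)

        stage("feature representation")
        for (a, b), res in dm_results.items():
            sig = res[res["status"].isin(["hyper", "hypo"])]
            dmc_features: Counter = Counter()
            for _, r in sig.iterrows():
                label, _ = index.annotate_position(r["contig"], int(r["pos"]))
                dmc_features[label] += 1
            rep = enrichment.feature_representation(dmc_features, bg_features)
            _write(rep, outdir / f"representation_{_cmp_tag(a, b)}.tsv")

        stage("RRHO")
        (ra, rb), (rc, rd) = config.rrho_pair
        list_a = rrho.ranked_list(de_results[(ra, rb)])
        list_b = rrho.ranked_list(de_results[(rc, rd)])
        maps = rrho.rrho_map(list_a, list_b, config.rrho_step)
        for quad, m in maps.items():
            mat = pd.DataFrame(m.neg_log10_adj_p, index=m.thresholds_a,
                               columns=m.thresholds_b)
            _write(mat, outdir / f"rrho_{quad}.tsv", index=True)
            pd.DataFrame({"gene_id": m.genes}).to_csv(
                outdir / f"rrho_{quad}_genes.tsv", sep="\t", index=False
            )
        run_log.append(
            "RRHO overlap sizes: "
            + ", ".join(f"{q}={len(m.genes)}" for q, m in maps.items())
        )

        stage("DEG clustering")
        deg_union: list[str] = []
        for res in de_results.values():
            deg_union.extend(res.index[res["is_deg"]])
        deg_union = sorted(set(deg_union))
        if len(deg_union) >= config.kmeans_k:
            clusters = de.zscore_and_cluster(deg_union, filtered, config.kmeans_k,
                                             seed=config.seed)
            _write(clusters, outdir / "deg_clusters.tsv", index=True)
            run_log.append(f"DEG union clustered: {len(deg_union)} genes")
        else:
            warn_counts["clustering_skipped"] += 1
            run_log.append(
                f"DEG union too small to cluster ({len(deg_union)} < k={config.kmeans_k})"
            )

        stage("integration")
        region_m = {"gene_body": config.quantiles_gene_body,
                    "promoter": config.quantiles_promoter}
        joint_sets: dict[tuple[str, str], list[str]] = {}
        for (a, b) in config.comparisons:
            degs, dmcs = de_results[(a, b)], dm_results[(a, b)]
            for region, m in region_m.items():
                pairs = integrate.pair_deg_dmc(degs, dmcs, index, region)
                _write(pairs, outdir / f"pairs_{region}_{_cmp_tag(a, b)}.tsv")
                if pairs.empty:
                    continue
                m_eff = m
                while m_eff > 1:
                    try:
                        strat = integrate.quantile_stratify(pairs, m_eff)
                        break
                    except ValueError:
                        m_eff -= 1
                else:
                    warn_counts["quantiles_skipped"] += 1
                    continue
                if m_eff < m:
                    warn_counts["quantiles_reduced"] += 1
                    run_log.append(
                        f"integration {_cmp_tag(a, b)}/{region}: quantiles reduced {m}->{m_eff}"
                    )
                corr = integrate.spearman_by_quantile(strat, config.p_threshold)
                _write(corr, outdir / f"correlation_{region}_{_cmp_tag(a, b)}.tsv")
            joint_sets[(a, b)] = integrate.joint_change_genes(degs, dmcs, index)
            pd.DataFrame({"gene_id": joint_sets[(a, b)]}).to_csv(
                outdir / f"joint_change_genes_{_cmp_tag(a, b)}.tsv", sep="\t", index=False
            )

        stage("over-representation")
        if genesets is not None:
            domain = list(filtered.gene_ids)
            if orthologs is not None:
                domain, unmapped = enrichment.map_orthologs(domain, orthologs)
                warn_counts["unmapped_genes"] += len(unmapped)
            for (a, b) in config.comparisons:
                for kind, genes_list in (
                    ("deg", sorted(de_results[(a, b)].index[de_results[(a, b)]["is_deg"]])),
                    ("joint", joint_sets[(a, b)]),
                ):
                    if orthologs is not None:
                        genes_list, unmapped = enrichment.map_orthologs(genes_list, orthologs)
                        warn_counts["unmapped_genes"] += len(unmapped)
                    if not genes_list:
                        continue
                    res = enrichment.ora(genes_list, genesets, domain,
                                         config.fdr_threshold)
                    _write(res, outdir / f"ora_{kind}_{_cmp_tag(a, b)}.tsv")

        stage("provenance")
        config.to_yaml(outdir / "config_resolved.yaml")
        run_log.append("warnings: " + (
            ", ".join(f"{k}={v}" for k, v in sorted(warn_counts.items())) or "none"
        ))
        (outdir / "run.log").write_text("\n".join(run_log) + "\n")
        return outdir
    except PipelineError:
        raise
    except Exception as exc:  # surface the failing stage
        current = next((line for line in reversed(run_log) if line.startswith("stage:")),
                       "stage: ?")
        raise PipelineError(f"{current} failed: {exc}") from exc
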