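"""Synthetic four-group study generator.

Emulates the structure of a dentate-gyrus RRBS + RNA-seq study of prairie
vole paternal behaviour: four groups — "Attacker", "Parental", "Father",
"Mother" — with 6/6/5/6 biological replicates, gene-level negative-binomial
expression counts with planted fold changes, and CpG-level beta-binomial
methylation counts restricted to digest-capturable sites with planted
methylation differences.  An optional Gaussian-copula coupling ties promoter
methylation change anti-monotonically to expression change for a subset of
genes, so the integration stage has a recoverable signal.

Everything is driven by one seeded numpy Generator, so a fixed seed gives a
byte-identical study.  Methylation is simulated only at CpGs the in-silico
digest can capture, which makes the representation test's urn model exact by
construction.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .digest import BackgroundCpGSet, digest_genome
from .types import CountMatrix, GeneModel, GenomeSequence, MethCountTable

log = logging.getLogger(__name__)

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("Attacker", 6),
    ("Parental", 6),
    ("Father", 5),
    ("Mother", 6),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated study design."""

    seed: int = 0
    # genome
    n_contigs: int = 4
    contig_len: int = 2_500_000
    ccgg_rate: float = 0.00018     # planted MspI sites per bp (~20k capturable CpGs)
    n_genes: int = 5000
    gene_len_range: tuple[int, int] = (600, 1200)
    # groups: label -> number of samples
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    # expression
    de_fraction: float = 0.1
    de_log2fc_mean: float = 1.0
    de_log2fc_sd: float = 0.25
    nb_dispersion: float = 0.1
    mean_count_log_mean: float = math.log(100.0)
    mean_count_log_sd: float = 1.0
    size_factor_sd: float = 0.1
    # methylation
    cpg_flank: int = 100
    dmc_fraction: float = 0.05
    dmc_delta_mean: float = 0.3
    dmc_delta_sd: float = 0.05
    betabin_dispersion: float = 0.05
    coverage_mean: float = 30.0
    # promoter-methylation / expression coupling
    coupling_rho: float = 0.0
    promoter_up: int = 2000

    def validate(self) -> None:
        for name in ("de_fraction", "dmc_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion < 0 or self.betabin_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if not (0.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho outside [0, 1]")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} needs >= 2 samples")

    @property
    def sample_table(self) -> dict[str, str]:
        out = {}
        for label, n in self.groups:
            for i in range(1, n + 1):
                out[f"{label}_{i}"] = label
        return out


@dataclass
class GroundTruth:
    """Planted effects: what the downstream stages should recover."""

    # gene_id -> (affected group, log2FC applied in that group)
    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    # (contig, pos) -> (affected group, methylation delta applied in that group)
    dmcs: dict[tuple[str, int], tuple[str, float]] = field(default_factory=dict)
    coupled_genes: list[str] = field(default_factory=list)

    def de_log2fc(self, group_x: str, group_y: str) -> pd.Series:
        """Planted log2FC of comparison X vs Y per planted gene."""
        out = {}
        for gene, (grp, lfc) in self.de_genes.items():
            eff = (lfc if grp == group_x else 0.0) - (lfc if grp == group_y else 0.0)
            if eff != 0.0:
                out[gene] = eff
        return pd.Series(out, dtype=float)

    def dmc_delta(self, group_x: str, group_y: str) -> dict[tuple[str, int], float]:
        """Planted methylation delta of comparison X vs Y per planted CpG."""
        out = {}
        for site, (grp, delta) in self.dmcs.items():
            eff = (delta if grp == group_x else 0.0) - (delta if grp == group_y else 0.0)
            if eff != 0.0:
                out[site] = eff
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": {g: [grp, lfc] for g, (grp, lfc) in self.de_genes.items()},
            "dmcs": {f"{c}:{p}": [grp, d] for (c, p), (grp, d) in self.dmcs.items()},
            "coupled_genes": self.coupled_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        de = {g: (grp, float(lfc)) for g, (grp, lfc) in payload["de_genes"].items()}
        dmcs = {}
        for key, (grp, d) in payload["dmcs"].items():
            contig, pos = key.rsplit(":", 1)
            dmcs[(contig, int(pos))] = (grp, float(d))
        return cls(de, dmcs, list(payload["coupled_genes"]))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_contig(rng: np.random.Generator, length: int, ccgg_rate: float) -> str:
    """Random DNA free of spontaneous CCGG, with motifs planted at the rate.

    Spontaneous CCGG occurrences are destroyed by flipping their first C (the
    internal CpG survives, keeping CpG density realistic), so a rate of zero
    yields a genome the digest cannot capture at all.
    """
    arr = rng.choice(_BASES, size=length).copy()
    seq = arr.tobytes().decode()
    for _ in range(20):
        hits = [m.start() for m in re.finditer("(?=CCGG)", seq)]
        if not hits:
            break
        b = bytearray(seq, "ascii")
        for h in hits:
            b[h] = ord("A")
        seq = b.decode()
    n_sites = rng.poisson(ccgg_rate * length)
    if n_sites > 0:
        positions = rng.choice(np.arange(4, length - 8), size=n_sites, replace=False)
        b = bytearray(seq, "ascii")
        for p in sorted(positions):
            b[p : p + 4] = b"CCGG"
        seq = b.decode()
    return seq


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Random contigs with plantable digest sites plus non-overlapping genes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contigs = [
        GenomeSequence(f"chr{i + 1}", _random_contig(rng, config.contig_len, config.ccgg_rate))
        for i in range(config.n_contigs)
    ]

    lo, hi = config.gene_len_range
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for contig, n_genes_c in zip(contigs, per_contig):
        lengths = rng.integers(lo, hi + 1, size=n_genes_c)
        slack = config.contig_len - int(lengths.sum())
        if slack < n_genes_c + 1:
            raise ValueError(
                f"contig length {config.contig_len} cannot pack {n_genes_c} genes "
                f"of mean length {(lo + hi) / 2:.0f}"
            )
        gaps = rng.multinomial(slack, np.ones(n_genes_c + 1) / (n_genes_c + 1))
        cursor = 0
        for length, gap in zip(lengths, gaps[:-1]):
            start = cursor + int(gap)
            end = start + int(length)
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            exons = _split_exons(rng, start, end, n_exons)
            gid += 1
            genes.append(
                GeneModel(f"g{gid:05d}", contig.contig_name, strand, start, end, exons)
            )
    return contigs, genes


def _split_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> tuple[tuple[int, int], ...]:
    length = end - start
    if n_exons == 1 or length < 6 * n_exons:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = [start, *[start + int(c) for c in cuts], end]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append((bounds[i], bounds[i + 1]))
    return tuple(exons)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def plant_de_truth(
    config: SimulationConfig, gene_ids: list[str], rng: np.random.Generator
) -> GroundTruth:
    """Choose DE genes, affected groups and planted log2FCs."""
    truth = GroundTruth()
    n_de = int(round(config.de_fraction * len(gene_ids)))
    if n_de == 0:
        return truth
    chosen = rng.choice(len(gene_ids), size=n_de, replace=False)
    labels = [g for g, _ in config.groups]
    for i in sorted(chosen):
        grp = labels[int(rng.integers(len(labels)))]
        mag = abs(rng.normal(config.de_log2fc_mean, config.de_log2fc_sd))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.de_genes[gene_ids[int(i)]] = (grp, sign * mag)
    return truth


def simulate_expression(
    config: SimulationConfig,
    gene_ids: list[str],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """NB counts: mean_g × sizefactor_s × 2^(planted log2FC in affected group)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = config.sample_table
    sample_ids = list(samples)
    base = rng.lognormal(config.mean_count_log_mean, config.mean_count_log_sd,
                         size=len(gene_ids))
    sf = rng.lognormal(0.0, config.size_factor_sd, size=len(sample_ids))
    lfc = np.zeros((len(gene_ids), len(sample_ids)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gene, (grp, l2) in truth.de_genes.items():
        cols = [j for j, s in enumerate(sample_ids) if samples[s] == grp]
        lfc[gene_pos[gene], cols] = l2
    mu = base[:, None] * sf[None, :] * 2.0 ** lfc
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"
    return CountMatrix(df, samples)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def _promoter_cpgs(
    genes: list[GeneModel], background: BackgroundCpGSet, promoter_up: int
) -> dict[str, list[tuple[str, int]]]:
    """Background CpGs falling in each gene's promoter window."""
    by_contig: dict[str, np.ndarray] = {}
    for contig in {c for c, _ in background.positions}:
        by_contig[contig] = np.array(
            sorted(p for c, p in background.positions if c == contig)
        )
    out: dict[str, list[tuple[str, int]]] = {}
    for g in genes:
        pos = by_contig.get(g.contig)
        if pos is None or len(pos) == 0:
            continue
        if g.strand == "+":
            lo, hi = max(0, g.start - promoter_up), g.start
        else:
            lo, hi = g.end, g.end + promoter_up
        i, j = np.searchsorted(pos, [lo, hi])
        if j > i:
            out[g.gene_id] = [(g.contig, int(p)) for p in pos[i:j]]
    return out


def coupled_promoter_deltas(
    lfc: np.ndarray, rho: float, rng: np.random.Generator, delta_scale: float = 0.35
) -> np.ndarray:
    """Promoter methylation deltas anti-monotone with expression change.

    Ranks of the planted log2FCs are mapped to normal scores, mixed with
    Gaussian noise through a copula of strength ``rho`` (sign-flipped, so
    higher expression pairs with lower promoter methylation), and pushed
    through a monotone map onto (−delta_scale, +delta_scale).
    """
    lfc = np.asarray(lfc, dtype=float)
    ranks = pd.Series(lfc).rank().to_numpy()
    z1 = norm.ppf(ranks / (len(ranks) + 1.0))
    z2 = -rho * z1 + math.sqrt(1.0 - rho**2) * rng.normal(size=len(z1))
    return delta_scale * (2.0 * norm.cdf(z2) - 1.0)


def plant_dm_truth(
    config: SimulationConfig,
    background: BackgroundCpGSet,
    truth: GroundTruth,
    rng: np.random.Generator,
    genes: list[GeneModel] | None = None,
) -> GroundTruth:
    """Choose planted DMCs; couple promoter CpGs of DE genes when requested.

    Coupling: for each coupled gene, its promoter CpGs get a methylation
    delta anti-monotone with the planted log2FC through a Gaussian copula of
    strength ``coupling_rho``, applied in the gene's own affected group.
    """
    sites = background.sorted_positions()
    n_dmc = int(round(config.dmc_fraction * len(sites)))
    labels = [g for g, _ in config.groups]
    if n_dmc > 0:
        chosen = rng.choice(len(sites), size=n_dmc, replace=False)
        for i in sorted(chosen):
            grp = labels[int(rng.integers(len(labels)))]
            mag = abs(rng.normal(config.dmc_delta_mean, config.dmc_delta_sd))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.dmcs[sites[int(i)]] = (grp, sign * mag)

    if config.coupling_rho > 0 and genes is not None and truth.de_genes:
        promoter_map = _promoter_cpgs(genes, background, config.promoter_up)
        coupled = sorted(g for g in truth.de_genes if g in promoter_map)
        if coupled:
            lfc = np.array([truth.de_genes[g][1] for g in coupled])
            delta = coupled_promoter_deltas(lfc, config.coupling_rho, rng)
            for g, d in zip(coupled, delta):
                grp = truth.de_genes[g][0]
                for site in promoter_map[g]:
                    truth.dmcs[site] = (grp, float(d))
            truth.coupled_genes = coupled
    return truth


def simulate_methylation(
    config: SimulationConfig,
    background: BackgroundCpGSet,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> MethCountTable:
    """Beta-binomial methylation counts at every background CpG.

    Baseline methylation is a bimodal mixture (mostly low or high, as CpG
    methylation is in practice); planted DMCs shift the affected group's
    level by the planted delta, clamped to [0.01, 0.99] with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = background.sorted_positions()
    samples = config.sample_table
    sample_ids = list(samples)
    n_sites, n_samp = len(sites), len(sample_ids)
    u = rng.random(n_sites)
    pi0 = np.where(
        u < 0.4,
        rng.beta(1, 9, size=n_sites),
        np.where(u < 0.8, rng.beta(9, 1, size=n_sites), rng.beta(5, 5, size=n_sites)),
    )
    pi = np.tile(np.clip(pi0, 0.01, 0.99)[:, None], (1, n_samp))
    n_clamped = 0
    site_pos = {s: i for i, s in enumerate(sites)}
    for site, (grp, delta) in truth.dmcs.items():
        i = site_pos.get(site)
        if i is None:
            continue
        cols = [j for j, s in enumerate(sample_ids) if samples[s] == grp]
        shifted = pi[i, cols[0]] + delta
        clamped = min(max(shifted, 0.01), 0.99)
        if clamped != shifted:
            n_clamped += 1
        pi[i, cols] = clamped
    if n_clamped:
        warnings.warn(f"{n_clamped} planted deltas clamped to keep levels in [0.01, 0.99]")

    coverage = rng.poisson(config.coverage_mean, size=(n_sites, n_samp))
    phi = config.betabin_dispersion
    if phi > 0:
        a = pi * (1 - phi) / phi
        b = (1 - pi) * (1 - phi) / phi
        p_draw = rng.beta(a, b)
    else:
        p_draw = pi
    n_meth = rng.binomial(coverage, p_draw)

    contigs = np.array([c for c, _ in sites])
    poss = np.array([p for _, p in sites])
    rec = pd.DataFrame(
        {
            "contig": np.repeat(contigs, n_samp),
            "pos": np.repeat(poss, n_samp),
            "sample_id": np.tile(sample_ids, n_sites),
            "n_meth": n_meth.ravel(),
            "n_unmeth": (coverage - n_meth).ravel(),
        }
    )
    return MethCountTable(rec, samples)


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: list[GenomeSequence]
    genes: list[GeneModel]
    counts: CountMatrix
    meth: MethCountTable
    background: BackgroundCpGSet
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full study from one seed: genome, annotation, expression
    counts, digest background and methylation counts, plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, genes = simulate_genome(config, rng)
    gene_ids = [g.gene_id for g in genes]
    truth = plant_de_truth(config, gene_ids, rng)
    counts = simulate_expression(config, gene_ids, truth, rng)
    background = digest_genome(genome, flank=config.cpg_flank)
    truth = plant_dm_truth(config, background, truth, rng, genes=genes)
    meth = simulate_methylation(config, background, truth, rng)
    log.info(
        "simulated study: %d genes, %d capturable CpGs, %d planted DEGs, %d planted DMCs",
        len(genes), len(background), len(truth.de_genes), len(truth.dmcs),
    )
    return SimulatedStudy(config, genome, genes, counts, meth, background, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write FASTA, GTF, counts TSV, per-sample coverage TSVs and truth JSON."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(study.genome, outdir / "genome.fa")
    mio.write_gtf(study.genes, outdir / "annotation.gtf")
    mio.write_counts(study.counts, outdir / "counts.tsv")
    with open(outdir / "groups.tsv", "wt") as fh:
        for s, g in study.counts.group_of.items():
            fh.write(f"{s}\t{g}\n")
    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for s in study.meth.sample_ids:
        rec = study.meth.records[study.meth.records["sample_id"] == s]
        mio.write_meth_coverage(rec, cov_dir / f"{s}.cov")
    study.truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "wt") as fh:
        json.dump(asdict(study.config), fh, indent=1, default=list)
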