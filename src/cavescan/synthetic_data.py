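"""Synthetic two-population fixtures with known ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
Balding-Nichols genotypes with planted high-divergence genes, per-SNP
selection statistics with planted within-gene shifts, and paired fish/human
differential-expression tables with a planted direction-concordance rate and
a planted gene-set enrichment.

The divergence model is Balding-Nichols: each gene draws an ancestral
alternate-allele frequency p uniformly on [0.05, 0.95] (bounded away from
the edges so sites monomorphic in both populations do not dominate), and
each population's frequency is Beta-distributed with mean p and shape
parameters (p (1-F)/F, (1-p) (1-F)/F), where F is the gene's divergence
parameter — the background value for ordinary genes and the planted value
for outlier genes.  Diploid genotypes are binomial draws from the population
frequency, and genotypes are masked missing independently at a fixed rate.
F is the estimand of Weir-Cockerham F_ST under this model, which is what
makes estimator-recovery checks meaningful.

A single numpy Generator seeded from ``config.seed`` drives every draw, so
identical configs give byte-identical outputs; the seed is recorded in all
output file headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen_stats import GeneAnnotation, GenotypeDataset

__all__ = [
    "SimulationConfig",
    "SimulatedGenotypes",
    "SimulatedExpression",
    "gene_layout",
    "simulate_genotypes",
    "simulate_selection_stats",
    "simulate_de_tables",
    "selection_gene_set",
    "write_vcf",
    "write_genes_bed",
    "write_selection_stats",
    "write_de_table",
    "write_ortholog_map",
    "write_gene_set",
    "write_truth",
]

SITE_SPACING = 10  # bp between simulated SNPs within a gene
GENE_GAP = 100  # bp between consecutive simulated genes


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults emulate a mid-scale version of a two-morph resequencing and
    expression study: moderate background differentiation (F = 0.05) with a
    small fraction of strongly diverged genes (F = 0.6), ~5% missing
    genotypes, a 30% differentially expressed fraction with |log2FC| = 1.5,
    60% cross-species direction concordance among jointly DE genes, and a
    gene set whose significance probability is doubled.
    """

    seed: int = 0
    n_genes: int = 1000
    sites_per_gene: int = 50
    n_diploids_pop1: int = 25
    n_diploids_pop2: int = 25
    background_F: float = 0.05
    planted_outlier_fraction: float = 0.02
    planted_F: float = 0.6
    missing_rate: float = 0.05
    de_fraction: float = 0.3
    de_effect: float = 1.5
    concordance_rate: float = 0.6
    geneset_size: int = 200
    geneset_enrichment: float = 2.0

    def __post_init__(self) -> None:
        for name in ("planted_outlier_fraction", "missing_rate", "de_fraction",
                     "concordance_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("background_F", "planted_F"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"{name} must be strictly inside (0, 1), got {v}; "
                    "degenerate F is not supported"
                )
        if self.planted_outlier_fraction > 0 and self.planted_F <= self.background_F:
            raise ValueError("planted_F must exceed background_F when outliers are planted")
        if self.geneset_size > self.n_genes:
            raise ValueError("geneset_size cannot exceed n_genes")
        for name in ("n_genes", "sites_per_gene", "n_diploids_pop1",
                     "n_diploids_pop2", "geneset_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.geneset_enrichment < 0:
            raise ValueError("geneset_enrichment must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedGenotypes:
    """Genotype fixture bundle: counts table, raw matrices, layout, truth."""

    dataset: GenotypeDataset
    annotation: GeneAnnotation
    genotypes_pop1: np.ndarray  # (n_sites, n_diploids) in {0,1,2,-1}
    genotypes_pop2: np.ndarray
    truth: pd.DataFrame  # gene_id, chrom, start, end, is_planted, true_F
    config: SimulationConfig


@dataclass
class SimulatedExpression:
    """Expression fixture bundle: DE tables, ortholog map, gene set, truth."""

    fish_de: pd.DataFrame  # gene_id, log2fc, padj
    human_de: pd.DataFrame
    ortholog_map: pd.DataFrame  # human_gene, orthogroup, fish_paralog
    gene_set: list[str]  # human gene ids
    truth: pd.DataFrame  # per human gene: is_de, direction, in_gene_set
    paralog_truth: pd.DataFrame  # per fish paralog: is_de, direction, matches_human
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Genotypes under the Balding-Nichols model
# ---------------------------------------------------------------------------

def gene_layout(cfg: SimulationConfig) -> pd.DataFrame:
    """Lay genes end to end on one chromosome; SNPs every SITE_SPACING bp."""
    length = cfg.sites_per_gene * SITE_SPACING
    starts = np.arange(cfg.n_genes) * (length + GENE_GAP)
    return pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(cfg.n_genes)],
        "chrom": "chr1",
        "start": starts,
        "end": starts + length,
    })


def simulate_genotypes(config: SimulationConfig) -> SimulatedGenotypes:
    """Draw two-population genotypes with planted high-divergence genes.

    Gene outlier labels are assigned by a Bernoulli draw at
    ``planted_outlier_fraction``; planted genes use ``planted_F`` as their
    Balding-Nichols divergence parameter, all others ``background_F``.
    Returns the allele-count dataset, the gene annotation (no masks or
    indels — those are exercised with hand-built fixtures), the raw diploid
    genotype matrices (-1 for missing) and the per-gene truth table.
    """
    rng = config.rng()
    genes = gene_layout(config)
    n_g, n_s = config.n_genes, config.sites_per_gene
    is_planted = rng.random(n_g) < config.planted_outlier_fraction
    true_F = np.where(is_planted, config.planted_F, config.background_F)

    anc = rng.uniform(0.05, 0.95, size=(n_g, n_s))
    F = true_F[:, None]
    alpha = anc * (1.0 - F) / F
    beta = (1.0 - anc) * (1.0 - F) / F
    p1 = rng.beta(alpha, beta)
    p2 = rng.beta(alpha, beta)

    g1 = rng.binomial(2, p1[..., None], size=(n_g, n_s, config.n_diploids_pop1))
    g2 = rng.binomial(2, p2[..., None], size=(n_g, n_s, config.n_diploids_pop2))
    if config.missing_rate > 0:
        g1 = np.where(rng.random(g1.shape) < config.missing_rate, -1, g1)
        g2 = np.where(rng.random(g2.shape) < config.missing_rate, -1, g2)

    g1 = g1.reshape(n_g * n_s, config.n_diploids_pop1)
    g2 = g2.reshape(n_g * n_s, config.n_diploids_pop2)

    pos = (genes["start"].to_numpy()[:, None]
           + np.arange(n_s) * SITE_SPACING + 1).ravel()  # 1-based
    n1 = 2 * (g1 >= 0).sum(axis=1)
    n2 = 2 * (g2 >= 0).sum(axis=1)
    ac1 = np.where(g1 > 0, g1, 0).sum(axis=1)
    ac2 = np.where(g2 > 0, g2, 0).sum(axis=1)
    sites = pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "n1": n1, "ac1": ac1, "n2": n2, "ac2": ac2,
    })

    truth = genes.copy()
    truth["is_planted"] = is_planted
    truth["true_F"] = true_F
    annotation = GeneAnnotation(genes=genes)
    return SimulatedGenotypes(
        dataset=GenotypeDataset(sites),
        annotation=annotation,
        genotypes_pop1=g1,
        genotypes_pop2=g2,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Per-SNP selection statistics
# ---------------------------------------------------------------------------

def simulate_selection_stats(
    config: SimulationConfig,
    truth: pd.DataFrame,
    snps_per_gene: int = 5,
    shift: float = 5.0,
    n_shifted_per_gene: int = 3,
) -> pd.DataFrame:
    """Per-SNP raw selection statistics with planted within-gene signals.

    SNPs are placed evenly inside each gene interval of ``truth``.  Ordinary
    SNPs draw from a standard normal; in planted genes,
    ``n_shifted_per_gene`` of the gene's SNPs draw from N(shift, 1).  An
    empty or all-False truth table yields a pure-null table.  Columns:
    chrom, pos, stat.
    """
    if snps_per_gene < 1:
        raise ValueError("snps_per_gene must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    n_shift = min(n_shifted_per_gene, snps_per_gene)
    for g in truth.itertuples(index=False):
        span = g.end - g.start
        offsets = (np.arange(snps_per_gene) + 0.5) / snps_per_gene * span
        pos = (g.start + offsets).astype(np.int64) + 1  # 1-based
        stat = rng.standard_normal(snps_per_gene)
        if bool(getattr(g, "is_planted", False)):
            stat[:n_shift] += shift
        for p, s in zip(pos, stat):
            rows.append((g.chrom, int(p), float(s)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "stat"])


def selection_gene_set(
    config: SimulationConfig,
    truth: pd.DataFrame,
    size: int | None = None,
) -> list[str]:
    """A focal gene set in the genotype-gene universe, enriched for planted
    genes: every planted gene plus a deterministic draw of ordinary genes up
    to ``size`` (default ``min(geneset_size, n_genes)``)."""
    size = min(config.geneset_size, config.n_genes) if size is None else size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    planted = truth.loc[truth["is_planted"], "gene_id"].tolist()
    rest = truth.loc[~truth["is_planted"], "gene_id"].to_numpy()
    n_fill = max(0, size - len(planted))
    fill = rng.choice(rest, size=min(n_fill, rest.size), replace=False).tolist()
    return sorted(planted + fill)


# ---------------------------------------------------------------------------
# Differential-expression tables, ortholog map and gene set
# ---------------------------------------------------------------------------

def _null_padj(rng: np.random.Generator, n: int) -> np.ndarray:
    # adjusted p for non-DE genes: skewed toward 1 (Beta(2,1)) and kept
    # above the 0.05 call threshold so truth labels match downstream calls
    return 0.05 + 0.95 * rng.beta(2.0, 1.0, size=n)


def simulate_de_tables(config: SimulationConfig) -> SimulatedExpression:
    """Paired fish/human DE tables with planted concordance and enrichment.

    Each of ``n_genes`` human genes founds one orthogroup with 1-2 fish
    paralogs.  A human gene is differentially expressed with probability
    ``de_fraction`` (multiplied by ``geneset_enrichment``, capped at 1, for
    gene-set members); DE genes receive a random direction, log2 fold-change
    ``direction * de_effect`` plus N(0, 0.1) noise, and an adjusted p drawn
    below 0.05.  Fish paralogs of a DE human gene are DE with the same
    magnitude, matching the human direction with probability
    ``concordance_rate`` (independently per paralog); paralogs of non-DE
    human genes are null.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_genes
    human_ids = [f"HG{i:05d}" for i in range(n)]
    orthogroups = [f"OG{i:05d}" for i in range(n)]

    in_set = np.zeros(n, dtype=bool)
    in_set[rng.choice(n, size=config.geneset_size, replace=False)] = True

    p_de = np.where(
        in_set,
        np.minimum(1.0, config.de_fraction * config.geneset_enrichment),
        config.de_fraction,
    )
    is_de = rng.random(n) < p_de
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)

    human_lfc = np.where(
        is_de,
        direction * config.de_effect + rng.normal(0, 0.1, n),
        rng.normal(0, 0.1, n),
    )
    human_padj = np.where(is_de, rng.uniform(1e-6, 0.049, n), _null_padj(rng, n))
    human_de = pd.DataFrame({"gene_id": human_ids, "log2fc": human_lfc, "padj": human_padj})

    n_paralogs = rng.integers(1, 3, size=n)  # 1 or 2 paralogs per human gene
    map_rows, fish_rows, ptruth_rows = [], [], []
    for i, hg in enumerate(human_ids):
        for k in range(n_paralogs[i]):
            suffix = "ab"[k] if n_paralogs[i] > 1 else ""
            pid = f"fish{i:05d}{suffix}"
            map_rows.append((hg, orthogroups[i], pid))
            if is_de[i]:
                match = rng.random() < config.concordance_rate
                d = direction[i] if match else -direction[i]
                lfc = d * config.de_effect + rng.normal(0, 0.1)
                padj = rng.uniform(1e-6, 0.049)
            else:
                match = False
                d = 0.0
                lfc = rng.normal(0, 0.1)
                padj = float(_null_padj(rng, 1)[0])
            fish_rows.append((pid, lfc, padj))
            ptruth_rows.append((pid, hg, bool(is_de[i]), d, bool(match)))

    fish_de = pd.DataFrame(fish_rows, columns=["gene_id", "log2fc", "padj"])
    ortholog_map = pd.DataFrame(map_rows, columns=["human_gene", "orthogroup", "fish_paralog"])
    gene_set = [g for g, s in zip(human_ids, in_set) if s]
    truth = pd.DataFrame({
        "human_gene": human_ids, "orthogroup": orthogroups,
        "in_gene_set": in_set, "is_de": is_de,
        "direction": np.where(is_de, direction, 0.0),
    })
    paralog_truth = pd.DataFrame(
        ptruth_rows,
        columns=["fish_paralog", "human_gene", "is_de", "direction", "matches_human"],
    )
    return SimulatedExpression(fish_de, human_de, ortholog_map, gene_set,
                               truth, paralog_truth, config)


# ---------------------------------------------------------------------------
# Writers (minimal text formats; seed recorded in headers)
# ---------------------------------------------------------------------------

def write_vcf(sim: SimulatedGenotypes, path: str | Path) -> None:
    """Write diploid genotypes as a minimal VCF 4.2 (GT only, ./. missing)."""
    cfg = sim.config
    samples = ([f"surface{i:02d}" for i in range(cfg.n_diploids_pop1)]
               + [f"cave{i:02d}" for i in range(cfg.n_diploids_pop2)])
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cavescan-synthetic seed={cfg.seed}\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        sites = sim.dataset.sites
        for i, row in enumerate(sites.itertuples(index=False)):
            gts = [gt_strings[int(g)] for g in sim.genotypes_pop1[i]]
            gts += [gt_strings[int(g)] for g in sim.genotypes_pop2[i]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_genes_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def _write_tsv(df: pd.DataFrame, path: str | Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cavescan-synthetic seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_selection_stats(stats: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_tsv(stats, path, seed)


def write_de_table(de: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_tsv(de, path, seed)


def write_ortholog_map(omap: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_tsv(omap, path, seed)


def write_gene_set(gene_set: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set) + "\n")


def write_truth(truth: pd.DataFrame, path: str | Path, seed: int) -> None:
    _write_tsv(truth, path, seed)
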