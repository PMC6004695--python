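"""Per-gene nucleotide diversity, Weir-Cockerham F_ST and absolute divergence D_XY.

This module turns a two-population biallelic genotype table into per-gene
summary statistics after applying the site filters used throughout the
pipeline: repeat-masked intervals, indel-affected bases plus a 10 bp pad on
either side, and a minimum number of genotyped individuals per population.

Coordinate conventions
----------------------
VCF positions are 1-based; BED intervals (genes, masks, indels) are 0-based
half-open.  A site at 1-based position ``P`` belongs to interval ``[s, e)``
iff ``s <= P - 1 < e``.

Statistics
----------
Per-site nucleotide diversity within a population uses the unbiased sample
form ``pi = 2 p (1 - p) * n / (n - 1)`` with ``p`` the alternate-allele
frequency and ``n`` the non-missing allele count.  Absolute divergence per
site is ``d = p1 (1 - p2) + p2 (1 - p1)``.  F_ST uses the Weir-Cockerham
variance-components estimator on allele counts; the per-gene value defaults
to the ratio-of-sums ("weighted") form, with the mean-of-ratios form
available.  Per-gene pi and D_XY are means over retained sites, so genes of
different lengths stay comparable under genome-wide rank cut-offs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "GeneAnnotation",
    "FilterLog",
    "read_vcf",
    "read_bed",
    "filter_sites",
    "per_site_pi",
    "per_site_dxy",
    "per_site_wc_components",
    "pi_per_gene",
    "fst_per_gene",
    "dxy_per_gene",
    "compute_per_gene_stats",
    "write_per_gene_stats",
]

SITE_COLUMNS = ["chrom", "pos", "n1", "ac1", "n2", "ac2"]


@dataclass
class GenotypeDataset:
    """Biallelic site-level allele counts for two labelled populations.

    ``sites`` holds one row per site with columns ``chrom``, ``pos``
    (1-based), ``n1``/``n2`` (non-missing allele counts per population) and
    ``ac1``/``ac2`` (alternate-allele counts).  ``populations`` names the two
    populations, first entry playing the "surface" (reference-morph) role.
    """

    sites: pd.DataFrame
    populations: tuple[str, str] = ("surface", "cave")

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"sites table missing columns: {missing}")
        s = self.sites
        if ((s["ac1"] > s["n1"]) | (s["ac2"] > s["n2"])).any():
            raise ValueError("alternate-allele count exceeds allele count")
        if ((s[["n1", "n2", "ac1", "ac2"]] < 0).any()).any():
            raise ValueError("negative allele counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def swapped(self) -> "GenotypeDataset":
        """Return the dataset with the two populations' roles exchanged."""
        s = self.sites.rename(
            columns={"n1": "n2", "n2": "n1", "ac1": "ac2", "ac2": "ac1"}
        )[SITE_COLUMNS]
        return GenotypeDataset(s, (self.populations[1], self.populations[0]))


@dataclass
class GeneAnnotation:
    """Gene intervals plus repeat-mask and indel-exclusion intervals.

    All three tables use BED conventions (0-based half-open).  ``indels``
    spans cover the bases affected by each indel; the surrounding pad is
    applied by :func:`filter_sites`, not stored here.
    """

    genes: pd.DataFrame
    masks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    indels: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        for name in ("genes", "masks", "indels"):
            df = getattr(self, name)
            need = {"chrom", "start", "end"} - set(df.columns)
            if need:
                raise ValueError(f"{name} table missing columns: {sorted(need)}")
            if ((df["end"] - df["start"]) < 0).any():
                raise ValueError(f"{name}: negative-length interval")
        if "gene_id" not in self.genes.columns:
            raise ValueError("genes table needs a gene_id column")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")


@dataclass
class FilterLog:
    """Counts of sites removed by each filter rule, in application order."""

    n_input: int
    removed_masked: int
    removed_indel_adjacent: int
    removed_low_coverage: int
    n_retained: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, with_name: bool = False) -> pd.DataFrame:
    """Read a BED3/BED4 file into a DataFrame (0-based half-open)."""
    names = ["chrom", "start", "end"] + (["gene_id"] if with_name else [])
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=names, usecols=range(len(names)),
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def read_vcf(
    path: str | Path,
    pop1_samples: Sequence[str],
    pop2_samples: Sequence[str],
    populations: tuple[str, str] = ("surface", "cave"),
) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF into per-population allele counts.

    Multiallelic records and non-SNPs are skipped (the pipeline expects
    hard-filtered biallelic SNP input).  Missing genotypes (``./.``) simply
    reduce the non-missing allele count at that site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx1 = np.array([samples.index(s) for s in pop1_samples])
    idx2 = np.array([samples.index(s) for s in pop2_samples])
    if set(idx1) & set(idx2):
        raise ValueError("a sample appears in both populations")

    rows = []
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        gt = np.array(v.genotypes, dtype=np.int64)[:, :2]  # (n_samples, 2)
        a1 = gt[idx1].ravel()
        a2 = gt[idx2].ravel()
        a1 = a1[a1 >= 0]
        a2 = a2[a2 >= 0]
        rows.append((v.CHROM, v.POS, a1.size, int((a1 == 1).sum()),
                     a2.size, int((a2 == 1).sum())))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return GenotypeDataset(sites, populations)


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge possibly-overlapping intervals per chromosome; silent merge."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom"):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[str(chrom)] = (np.asarray(starts), np.asarray(ends))
    return out


def _in_intervals(sites: pd.DataFrame, merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Boolean mask: site (1-based pos) falls inside a merged 0-based interval."""
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom"):
        if str(chrom) not in merged:
            continue
        starts, ends = merged[str(chrom)]
        pos0 = grp["pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = j >= 0
        inside = np.zeros(len(grp), dtype=bool)
        inside[ok] = pos0[ok] < ends[j[ok]]
        hit[sites.index.get_indexer(grp.index)] = inside
    return hit


def filter_sites(
    dataset: GenotypeDataset,
    annotation: GeneAnnotation,
    min_individuals: int = 6,
    indel_pad: int = 10,
) -> tuple[GenotypeDataset, FilterLog]:
    """Apply the site filters and return the retained subset plus a log.

    Removes, in order: sites inside repeat-mask intervals; sites within an
    indel-affected span or within ``indel_pad`` bases of one; sites where
    either population has fewer than ``min_individuals`` genotyped diploid
    individuals (i.e. fewer than ``2 * min_individuals`` non-missing
    alleles).  Mask/indel intervals on chromosomes absent from the dataset
    are ignored; annotation chromosomes never seen in the data trigger a
    warning.
    """
    sites = dataset.sites.reset_index(drop=True)
    n_input = len(sites)

    data_chroms = set(sites["chrom"].astype(str))
    for name in ("masks", "indels"):
        df = getattr(annotation, name)
        unknown = set(df["chrom"].astype(str)) - data_chroms
        if unknown:
            warnings.warn(
                f"{name}: intervals on chromosomes absent from the dataset "
                f"ignored: {sorted(unknown)[:5]}",
                stacklevel=2,
            )

    keep = np.ones(n_input, dtype=bool)

    masked = _in_intervals(sites, _merge_intervals(annotation.masks)) if len(annotation.masks) else np.zeros(n_input, bool)
    removed_masked = int((keep & masked).sum())
    keep &= ~masked

    if len(annotation.indels):
        padded = annotation.indels.copy()
        padded["start"] = np.maximum(padded["start"] - indel_pad, 0)
        padded["end"] = padded["end"] + indel_pad
        near_indel = _in_intervals(sites, _merge_intervals(padded))
    else:
        near_indel = np.zeros(n_input, bool)
    removed_indel = int((keep & near_indel).sum())
    keep &= ~near_indel

    min_alleles = 2 * min_individuals
    low = (sites["n1"].to_numpy() < min_alleles) | (sites["n2"].to_numpy() < min_alleles)
    removed_low = int((keep & low).sum())
    keep &= ~low

    retained = GenotypeDataset(sites.loc[keep].reset_index(drop=True), dataset.populations)
    log = FilterLog(n_input, removed_masked, removed_indel, removed_low, retained.n_sites)
    return retained, log


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def per_site_pi(n: np.ndarray, ac: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity; NaN where n < 2."""
    n = np.asarray(n, dtype=float)
    ac = np.asarray(ac, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ac / n
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    pi[n < 2] = np.nan
    return pi


def per_site_dxy(n1, ac1, n2, ac2) -> np.ndarray:
    """Per-site absolute divergence p1(1-p2) + p2(1-p1); NaN where a
    population has no data."""
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.asarray(ac1, float) / n1
        p2 = np.asarray(ac2, float) / n2
        d = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    d[(n1 < 1) | (n2 < 1)] = np.nan
    return d


def per_site_wc_components(n1, ac1, n2, ac2) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per site for two populations.

    Uses the allele-count (analysis-of-variance) form of the estimator with
    alleles as sampling units: with per-population allele counts ``n_i`` and
    frequencies ``p_i``,

        MSP = sum n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum n_i p_i (1 - p_i) / (n_tot - r)
        n_c = (n_tot - sum n_i^2 / n_tot) / (r - 1)

    per-site numerator ``a = MSP - MSG`` and denominator
    ``MSP + (n_c - 1) MSG``; the per-site estimate is their ratio.  Sites
    monomorphic in both populations have zero numerator and denominator and
    contribute nothing to ratio-of-sums aggregation.  Returns NaN components
    where either population has fewer than 2 alleles.
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    ac1 = np.asarray(ac1, float); ac2 = np.asarray(ac2, float)
    r = 2.0
    nt = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / n1
        p2 = ac2 / n2
        pbar = (ac1 + ac2) / nt
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1.0)
        msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (nt - r)
        nc = (nt - (n1 ** 2 + n2 ** 2) / nt) / (r - 1.0)
        num = msp - msg
        den = msp + (nc - 1.0) * msg
    bad = (n1 < 2) | (n2 < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


# ---------------------------------------------------------------------------
# Gene assignment and per-gene aggregation
# ---------------------------------------------------------------------------

def _sites_in_gene(sites: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Indices (into ``sites``) of sites inside gene interval [start, end)."""
    grp = sites.index[sites["chrom"].astype(str) == str(chrom)]
    if len(grp) == 0:
        return np.array([], dtype=np.int64)
    pos0 = sites.loc[grp, "pos"].to_numpy() - 1
    sel = (pos0 >= start) & (pos0 < end)
    return grp.to_numpy()[sel]


def _gene_site_index(sites: pd.DataFrame, genes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map gene_id -> row indices of sites in the gene (overlaps allowed)."""
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("pos") for c, g in sites.groupby("chrom")
    }
    for row in genes.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in by_chrom:
            out[row.gene_id] = np.array([], dtype=np.int64)
            continue
        g = by_chrom[chrom]
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start + 1, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        out[row.gene_id] = g.index.to_numpy()[lo:hi]
    return out


def _nanmean_or_nan(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(x.mean()) if x.size else float("nan")


def pi_per_gene(dataset: GenotypeDataset, annotation: GeneAnnotation, population: int | str = 0) -> pd.Series:
    """Per-gene mean per-site nucleotide diversity for one population.

    ``population`` is an index (0/1) or one of the dataset's labels.  Genes
    with no retained, evaluable sites are NaN.
    """
    if isinstance(population, str):
        population = dataset.populations.index(population)
    n_col, ac_col = ("n1", "ac1") if population == 0 else ("n2", "ac2")
    sites = dataset.sites.reset_index(drop=True)
    pi = per_site_pi(sites[n_col].to_numpy(), sites[ac_col].to_numpy())
    idx = _gene_site_index(sites, annotation.genes)
    return pd.Series(
        {gid: _nanmean_or_nan(pi[rows]) for gid, rows in idx.items()},
        name=f"pi_{dataset.populations[population]}",
    )


def dxy_per_gene(dataset: GenotypeDataset, annotation: GeneAnnotation) -> pd.Series:
    """Per-gene mean per-site absolute divergence; symmetric in populations."""
    sites = dataset.sites.reset_index(drop=True)
    d = per_site_dxy(sites["n1"], sites["ac1"], sites["n2"], sites["ac2"])
    idx = _gene_site_index(sites, annotation.genes)
    return pd.Series({gid: _nanmean_or_nan(d[rows]) for gid, rows in idx.items()}, name="dxy")


def fst_per_gene(
    dataset: GenotypeDataset,
    annotation: GeneAnnotation,
    method: str = "weighted",
) -> pd.Series:
    """Per-gene Weir-Cockerham F_ST.

    ``method="weighted"`` (default) is the ratio-of-sums form: the per-gene
    estimate is the sum of per-site numerator components over the sum of
    denominator components.  ``method="mean"`` averages per-site ratios over
    polymorphic sites instead.  Genes whose denominator sums to zero (no
    polymorphic retained sites) are NaN.  Estimates are not clamped and may
    be slightly negative.
    """
    if method not in ("weighted", "mean"):
        raise ValueError("method must be 'weighted' or 'mean'")
    sites = dataset.sites.reset_index(drop=True)
    num, den = per_site_wc_components(sites["n1"], sites["ac1"], sites["n2"], sites["ac2"])
    idx = _gene_site_index(sites, annotation.genes)
    out = {}
    for gid, rows in idx.items():
        nn, dd = num[rows], den[rows]
        ok = ~np.isnan(dd)
        nn, dd = nn[ok], dd[ok]
        if method == "weighted":
            dsum = dd.sum()
            out[gid] = float(nn.sum() / dsum) if dd.size and dsum != 0 else float("nan")
        else:
            poly = dd != 0
            out[gid] = float((nn[poly] / dd[poly]).mean()) if poly.any() else float("nan")
    return pd.Series(out, name="fst")


def compute_per_gene_stats(
    dataset: GenotypeDataset,
    annotation: GeneAnnotation,
    fst_method: str = "weighted",
) -> pd.DataFrame:
    """All per-gene statistics in one table.

    Columns: gene_id, chrom, start, end, n_retained_sites, pi_pop1, pi_pop2,
    fst, dxy.  Genes with no retained sites keep their row with NaN
    statistics (a missing marker, never zeros).
    """
    sites = dataset.sites.reset_index(drop=True)
    idx = _gene_site_index(sites, annotation.genes)
    df = annotation.genes[["gene_id", "chrom", "start", "end"]].copy()
    df["n_retained_sites"] = df["gene_id"].map(lambda g: len(idx[g]))
    df = df.set_index("gene_id")
    df["pi_pop1"] = pi_per_gene(dataset, annotation, 0)
    df["pi_pop2"] = pi_per_gene(dataset, annotation, 1)
    df["fst"] = fst_per_gene(dataset, annotation, method=fst_method)
    df["dxy"] = dxy_per_gene(dataset, annotation)
    return df.reset_index()


def write_per_gene_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene statistics TSV with missing values as NA."""
    stats.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
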