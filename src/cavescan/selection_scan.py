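"""Per-gene selection calls from externally computed per-SNP statistics.

The pipeline consumes raw per-SNP selection-scan statistics (e.g. hapFLK
output) rather than recomputing them: the haplotype model that produces them
is out of scope here.  Statistics are converted to p-values by fitting a
normal distribution genome wide — standardise each value by the genome-wide
mean and standard deviation and take the standard normal's upper-tail
probability (larger statistics indicate stronger selection signal; a
two-sided option is available).  A gene is called significant when at least
one SNP inside it has p below the threshold; genes containing no SNPs have
no data and are dropped from the output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popgen_stats import GeneAnnotation

__all__ = [
    "DegenerateStatisticsError",
    "read_selection_stats",
    "fit_normal_pvalues",
    "gene_selection_calls",
    "write_selection_calls",
]


class DegenerateStatisticsError(ValueError):
    """Raised when the genome-wide statistics cannot support a normal fit."""


def read_selection_stats(path: str | Path) -> pd.DataFrame:
    """Read a (chrom, pos, stat) TSV; a leading '#' header line is allowed."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "stat"} - set(df.columns)
    if need:
        raise ValueError(f"selection statistic table missing columns: {sorted(need)}")
    return df


def fit_normal_pvalues(stats: pd.DataFrame, two_sided: bool = False) -> pd.DataFrame:
    """Attach per-SNP p-values from a genome-wide normal fit.

    z = (x - mean) / sd with the sample standard deviation (ddof=1);
    p = P(Z > z) one-sided by default.  p-values are strictly inside (0, 1)
    and monotone decreasing in the raw statistic (one-sided).
    """
    x = stats["stat"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateStatisticsError(
            "need at least 2 distinct statistic values for the normal fit")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateStatisticsError("zero genome-wide standard deviation")
    z = (x - mu) / sd
    p = sps.norm.sf(np.abs(z)) * 2 if two_sided else sps.norm.sf(z)
    out = stats.copy()
    out["pvalue"] = np.clip(p, np.nextafter(0, 1), np.nextafter(1, 0))
    return out


def gene_selection_calls(
    pvalues: pd.DataFrame,
    annotation: GeneAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene minimum p and significance call.

    A SNP at 1-based position P belongs to gene [s, e) iff s <= P - 1 < e;
    SNPs inside overlapping genes count for every gene.  Output columns:
    gene_id, n_snps, min_p, significant.  Genes with no SNPs are absent.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    by_chrom = {str(c): g.sort_values("pos") for c, g in pvalues.groupby("chrom")}
    for gene in annotation.genes.itertuples(index=False):
        grp = by_chrom.get(str(gene.chrom))
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, gene.start + 1, side="left")
        hi = np.searchsorted(pos, gene.end, side="right")
        if hi <= lo:
            continue  # no data for this gene
        pv = grp["pvalue"].to_numpy()[lo:hi]
        rows.append((gene.gene_id, hi - lo, float(pv.min())))
    out = pd.DataFrame(rows, columns=["gene_id", "n_snps", "min_p"])
    out["significant"] = out["min_p"] < alpha
    return out


def write_selection_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.10g")
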