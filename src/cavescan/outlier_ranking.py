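"""Genome-wide dense ranking and multi-metric divergence-outlier calls.

Each per-gene metric (pi in both populations, F_ST, D_XY) is dense-ranked
genome wide: tied values share a rank and ranks are consecutive integers
from 1, higher rank meaning higher value.  A gene is a divergence outlier
when it meets any of three criteria — dense rank in the top 5% for F_ST,
top 20% for D_XY, or a within-gene selection p-value below 0.05 — unless it
falls among the 500 lowest-diversity genes in the surface population, which
are excluded from outlier calling because low diversity there may reflect
low recombination rather than divergence.

Top-X% is evaluated on dense ranks: a gene qualifies when its dense rank
exceeds (1 - X) * R_max, R_max being the largest dense rank for that metric.
Because tied genes share a dense rank, ties at the boundary share fate.
Genes missing a metric are left out of that metric's ranking ("no data")
but can still qualify through the other metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OutlierThresholds",
    "dense_rank",
    "classify_outliers",
    "write_outlier_calls",
]


@dataclass
class OutlierThresholds:
    """Cut-offs for divergence-outlier classification.

    fst_top_fraction / dxy_top_fraction: top tail of the dense-rank
    distribution that qualifies (defaults 5% and 20%; 5% for D_XY is a
    supported stricter alternative).  hapflk_alpha: per-gene selection-call
    threshold.  pi_exclude_count: number of lowest surface-pi genes excluded
    from outlier calling.
    """

    fst_top_fraction: float = 0.05
    dxy_top_fraction: float = 0.20
    hapflk_alpha: float = 0.05
    pi_exclude_count: int = 500

    def __post_init__(self) -> None:
        for name in ("fst_top_fraction", "dxy_top_fraction", "hapflk_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.pi_exclude_count < 0:
            raise ValueError("pi_exclude_count must be >= 0")


def dense_rank(values) -> np.ndarray:
    """Ascending dense ranks; ties share a rank, ranks consecutive from 1.

    e.g. [0.02, 0.03, 0.04, 0.04] -> [1, 2, 3, 3].  NaN entries are excluded
    from ranking and returned as NaN.  All-missing input is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.isnan(x).all():
        raise ValueError("dense_rank needs at least one non-missing value")
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    _, inv = np.unique(x[ok], return_inverse=True)
    out[ok] = inv + 1.0
    return out


def _top_flag(ranks: np.ndarray, top_fraction: float) -> np.ndarray:
    """True where dense rank exceeds (1 - top_fraction) * R_max; NaN -> False."""
    with np.errstate(invalid="ignore"):
        rmax = np.nanmax(ranks)
        return np.where(np.isnan(ranks), False, ranks > (1.0 - top_fraction) * rmax)


def classify_outliers(
    stats: pd.DataFrame,
    selection_calls: pd.DataFrame | None,
    thresholds: OutlierThresholds = OutlierThresholds(),
    recompute_after_pi_exclusion: bool = False,
) -> pd.DataFrame:
    """Combine per-gene metrics and selection calls into outlier calls.

    ``stats`` is the per-gene table (gene_id, pi_pop1, pi_pop2, fst, dxy);
    ``selection_calls`` the per-gene selection table (gene_id, significant),
    or None when no selection scan is available.  Ranks are computed over
    genes with data for each metric; by default the low-diversity exclusion
    is applied after ranking (``recompute_after_pi_exclusion=True`` reranks
    F_ST/D_XY with the excluded genes removed).

    Output columns: gene_id, rank_pi_pop1, rank_pi_pop2, rank_fst, rank_dxy,
    fst_outlier, dxy_outlier, hapflk_significant, pi_excluded, is_outlier,
    n_metrics_met.
    """
    df = stats[["gene_id", "pi_pop1", "pi_pop2", "fst", "dxy"]].copy()

    # lowest surface-pi genes; ties broken by gene id for determinism
    has_pi = df.dropna(subset=["pi_pop1"]).sort_values(["pi_pop1", "gene_id"])
    excluded_ids = set(has_pi["gene_id"].head(thresholds.pi_exclude_count))
    df["pi_excluded"] = df["gene_id"].isin(excluded_ids)

    for metric in ("pi_pop1", "pi_pop2", "fst", "dxy"):
        vals = df[metric].to_numpy()
        if recompute_after_pi_exclusion and metric in ("fst", "dxy"):
            vals = np.where(df["pi_excluded"].to_numpy(), np.nan, vals)
        if np.isnan(vals).all():
            df[f"rank_{metric}"] = np.nan
        else:
            df[f"rank_{metric}"] = dense_rank(vals)

    df["fst_outlier"] = _top_flag(df["rank_fst"].to_numpy(), thresholds.fst_top_fraction)
    df["dxy_outlier"] = _top_flag(df["rank_dxy"].to_numpy(), thresholds.dxy_top_fraction)

    if selection_calls is not None and len(selection_calls):
        sig_ids = set(selection_calls.loc[selection_calls["significant"], "gene_id"])
        df["hapflk_significant"] = df["gene_id"].isin(sig_ids)
    else:
        df["hapflk_significant"] = False

    any_flag = df["fst_outlier"] | df["dxy_outlier"] | df["hapflk_significant"]
    df["is_outlier"] = any_flag & ~df["pi_excluded"]
    df["n_metrics_met"] = (
        df[["fst_outlier", "dxy_outlier", "hapflk_significant"]].sum(axis=1).astype(int)
    )
    cols = ["gene_id", "rank_pi_pop1", "rank_pi_pop2", "rank_fst", "rank_dxy",
            "fst_outlier", "dxy_outlier", "hapflk_significant", "pi_excluded",
            "is_outlier", "n_metrics_met"]
    return df[cols]


def write_outlier_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
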