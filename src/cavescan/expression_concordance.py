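"""Cross-species differential-expression direction concordance.

Workflow: call a direction (up / down / not significant) for every gene in
a DE table from its log2 fold-change and Benjamini-Hochberg adjusted p;
summarise fish paralog calls at the orthogroup level (an orthogroup — the
set of fish paralogs sharing an ancestor with one human gene — is
significant when any member paralog is); and score, at the paralog level,
how often a fish gene's direction matches its human ortholog's direction in
an independent case-control comparison.  Human genes whose reports disagree
on direction are excluded from concordance and counted.

Conventions: fold-changes are case-vs-control (cave vs surface on the fish
side), so "up" means higher expression in the case condition in both
species and a sign match is direct evidence of a shared expression shift.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import ContingencyTable2x2, bonferroni, yates_chi_square

__all__ = [
    "ConcordanceResult",
    "bh_adjust",
    "call_directions",
    "read_de_table",
    "read_ortholog_map",
    "aggregate_human_reports",
    "orthogroup_summary",
    "concordance",
    "cross_model_comparison",
]

UP, DOWN, NS = "up", "down", "ns"


@dataclass
class ConcordanceResult:
    """Paralog-level direction agreement between fish and human DE calls."""

    n_jointly_de: int
    n_same_direction: int
    percent_same_direction: float
    per_gene: pd.DataFrame  # fish_paralog, human_gene, fish_dir, human_dir, same
    n_excluded_inconsistent: int

    def __str__(self) -> str:
        return (f"{self.n_same_direction} of {self.n_jointly_de} jointly DE "
                f"paralogs in the same direction ({self.percent_same_direction:.1f}%)")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted p_(i) = min over j >= i of (m / j) p_(j), capped at 1; the
    output is never below the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE TSV with columns gene_id, log2fc, padj ('#' comments ok)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if need:
        raise ValueError(f"DE table missing columns: {sorted(need)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("DE table has duplicate gene ids")
    return df


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"human_gene", "orthogroup", "fish_paralog"} - set(df.columns)
    if need:
        raise ValueError(f"ortholog map missing columns: {sorted(need)}")
    og_per_paralog = df.groupby("fish_paralog")["orthogroup"].nunique()
    if (og_per_paralog > 1).any():
        raise ValueError("a fish paralog maps to more than one orthogroup")
    return df


def call_directions(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene direction calls: 'up', 'down' or 'ns'.

    up iff padj < alpha and log2fc > 0; down iff padj < alpha and
    log2fc < 0.  Significant genes with exactly zero fold-change carry no
    direction; they are dropped with a warning.
    """
    df = table.copy()
    sig = df["padj"] < alpha
    zero_sig = sig & (df["log2fc"] == 0)
    if zero_sig.any():
        warnings.warn(
            f"{int(zero_sig.sum())} significant gene(s) with log2fc == 0 "
            "excluded (no direction)", stacklevel=2)
        df = df.loc[~zero_sig]
        sig = df["padj"] < alpha
    df["direction"] = np.where(~sig, NS, np.where(df["log2fc"] > 0, UP, DOWN))
    return df[["gene_id", "direction"]].reset_index(drop=True)


def aggregate_human_reports(reports: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-report human direction calls into one table.

    A gene significant in at least one report keeps that direction when all
    its significant calls agree; genes called up in one report and down in
    another are marked 'inconsistent' (excluded downstream and counted).
    Reports silent on a gene (ns or absent) do not veto an agreeing call.
    """
    frames = list(reports)
    if not frames:
        raise ValueError("no reports given")
    allcalls = pd.concat(frames, ignore_index=True)
    rows = []
    for gid, grp in allcalls.groupby("gene_id", sort=True):
        dirs = set(grp["direction"]) - {NS}
        if not dirs:
            rows.append((gid, NS))
        elif len(dirs) == 1:
            rows.append((gid, dirs.pop()))
        else:
            rows.append((gid, "inconsistent"))
    return pd.DataFrame(rows, columns=["gene_id", "direction"])


def orthogroup_summary(directions: pd.DataFrame, ortholog_map: pd.DataFrame) -> dict:
    """Summarise paralog direction calls per orthogroup.

    An orthogroup is significant iff at least one member paralog is; its
    direction is the shared direction when all significant members agree,
    'inconsistent' otherwise.  Paralogs absent from the map are reported in
    an unmapped bucket rather than silently dropped.  Returns per-orthogroup
    and rate-level summaries; the any-paralog rule is recorded in metadata.
    """
    dirmap = directions.set_index("gene_id")["direction"]
    mapped = ortholog_map[ortholog_map["fish_paralog"].isin(dirmap.index)]
    unmapped = sorted(set(dirmap.index) - set(ortholog_map["fish_paralog"]))

    rows = []
    for og, grp in mapped.groupby("orthogroup", sort=True):
        paralogs = grp["fish_paralog"].tolist()
        dirs = dirmap.loc[paralogs]
        sig_dirs = set(dirs[dirs != NS])
        n_sig = int((dirs != NS).sum())
        if not sig_dirs:
            og_dir = NS
        elif len(sig_dirs) == 1:
            og_dir = sig_dirs.pop()
        else:
            og_dir = "inconsistent"
        rows.append((og, len(paralogs), n_sig, n_sig > 0, og_dir))
    per_og = pd.DataFrame(rows, columns=[
        "orthogroup", "n_paralogs", "n_significant_paralogs",
        "orthogroup_significant", "orthogroup_direction"])

    n_par = int(per_og["n_paralogs"].sum())
    n_par_sig = int(per_og["n_significant_paralogs"].sum())
    n_og = len(per_og)
    n_og_sig = int(per_og["orthogroup_significant"].sum())
    return {
        "per_orthogroup": per_og,
        "n_orthogroups": n_og,
        "n_orthogroups_significant": n_og_sig,
        "orthogroup_percent_significant": 100.0 * n_og_sig / n_og if n_og else float("nan"),
        "n_paralogs": n_par,
        "n_paralogs_significant": n_par_sig,
        "paralog_percent_significant": 100.0 * n_par_sig / n_par if n_par else float("nan"),
        "unmapped_paralogs": unmapped,
        "significance_rule": "orthogroup significant iff any member paralog significant",
    }


def concordance(
    fish_directions: pd.DataFrame,
    human_directions: pd.DataFrame,
    ortholog_map: pd.DataFrame,
) -> ConcordanceResult:
    """Paralog-level direction concordance between fish and human calls.

    A fish paralog is jointly DE when both it and its mapped human gene have
    a direction; agreement is a sign match.  Human genes marked
    'inconsistent' (conflicting reports) are excluded and counted.  Each
    paralog of a human gene is scored independently.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    fish = fish_directions.set_index("gene_id")["direction"]
    human = human_directions.set_index("gene_id")["direction"]

    recs = []
    n_inconsistent = 0
    for row in ortholog_map.itertuples(index=False):
        fd = fish.get(row.fish_paralog, NS)
        hd = human.get(row.human_gene, NS)
        if hd == "inconsistent":
            n_inconsistent += 1
            continue
        if fd == NS or hd == NS:
            continue
        recs.append((row.fish_paralog, row.human_gene, fd, hd, fd == hd))
    per_gene = pd.DataFrame(
        recs, columns=["fish_paralog", "human_gene", "fish_dir", "human_dir", "same"])
    n_joint = len(per_gene)
    n_same = int(per_gene["same"].sum()) if n_joint else 0
    pct = 100.0 * n_same / n_joint if n_joint else float("nan")
    return ConcordanceResult(n_joint, n_same, pct, per_gene, n_inconsistent)


def cross_model_comparison(
    results: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Pairwise chi-square comparison of DE rates across models/datasets.

    ``results`` rows are (label, n_de, n_total).  Every pair is tested with
    the Yates-corrected 2x2 chi-square on (DE, not-DE) x (model A, model B)
    and p-values are Bonferroni-multiplied by the number of pairwise tests,
    capped at 1.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 models to compare")
    for label, n_de, n_total in results:
        if n_total <= 0:
            raise ValueError(f"model {label!r} has zero total genes")
        if not 0 <= n_de <= n_total:
            raise ValueError(f"model {label!r}: DE count outside [0, total]")
    pairs = list(itertools.combinations(range(len(results)), 2))
    rows = []
    for i, j in pairs:
        la, da, ta = results[i]
        lb, db, tb = results[j]
        table = ContingencyTable2x2(da, ta - da, db, tb - db)
        stat, df, p = yates_chi_square(table)
        rows.append((la, lb, stat, df, p, bonferroni(p, len(pairs))))
    return pd.DataFrame(rows, columns=[
        "model_a", "model_b", "chi_square", "df", "p_value", "p_bonferroni"])
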