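"""Gene-set enrichment and distribution-comparison statistics.

Covers the three inference tools used downstream of the divergence and
selection scans:

* 2x2 contingency tests of a focal gene set against the genome — the
  Yates-corrected chi-square statistic (the continuity-corrected form is the
  printed statistic in the study design this pipeline follows, with Fisher's
  exact p available as an option) plus the sample odds ratio with a Woolf
  log-scale 95% confidence interval;
* Kruskal-Wallis rank tests comparing a metric's distribution between gene
  groups;
* a bootstrap resampling null for expression enrichment: the observed
  percentage of significant genes in the set is compared against the
  percentages in repeated random samples of genes drawn without replacement
  from the expression universe, and reported as a percentile of that null.

The chi-square, Kruskal-Wallis and Benjamini-Hochberg formulas are written
out here rather than delegated, so the test suite can hold them against
scipy/statsmodels as genuinely independent references.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "BootstrapResult",
    "yates_chi_square",
    "fisher_exact_p",
    "odds_ratio",
    "kruskal_wallis",
    "bootstrap_expression_enrichment",
    "set_vs_genome_enrichment",
    "bonferroni",
    "read_gene_set",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): row 1 the focal gene set (significant /
    non-significant), row 2 the genome baseline."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class BootstrapResult:
    """Outcome of the resampling-null enrichment test (percent scale)."""

    observed_percent: float
    n_boot: int
    sample_size: int
    bootstrap_mean: float
    ci95_halfwidth: float
    percentile: float
    percentile_label: str
    seed: int | None

    def __str__(self) -> str:
        return (f"observed {self.observed_percent:.1f}% vs bootstrap "
                f"{self.bootstrap_mean:.1f} ± {self.ci95_halfwidth:.1f}% "
                f"({self.percentile_label} percentile)")


def _check_margins(t: ContingencyTable2x2) -> np.ndarray:
    obs = t.as_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero row or column total")
    return obs


def yates_chi_square(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Continuity-corrected chi-square for a 2x2 table.

    statistic = sum over cells of (max(|O - E| - 0.5, 0))^2 / E, p from the
    chi-square distribution with 1 degree of freedom.
    """
    obs = _check_margins(table)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float((adj ** 2 / exp).sum())
    return stat, 1, float(sps.chi2.sf(stat, 1))


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value (optional alternative to the
    chi-square p)."""
    _check_margins(table)
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, tuple[float, float]]:
    """Sample odds ratio ad/bc with a Woolf 95% confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell) for both the point estimate and the interval.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(orr) + 1.959963984540054 * se))
    return float(orr), (lo, hi)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average of the positions they span)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = _average_ranks(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie == 0:
        raise ValueError("all pooled values identical")
    h /= tie
    df = len(groups) - 1
    return float(h), df, float(sps.chi2.sf(h, df))


def bonferroni(p: float, n_tests: int) -> float:
    """Multiply p by the number of tests in the family, capped at 1."""
    return min(1.0, p * n_tests)


def bootstrap_expression_enrichment(
    gene_significance: Mapping[str, bool] | pd.Series,
    gene_set: Iterable[str],
    n_boot: int = 9999,
    sample_size: int = 500,
    seed: int | None = None,
    with_replacement: bool = False,
) -> BootstrapResult:
    """Score a gene set's significance rate against a resampling null.

    ``gene_significance`` maps every gene in the expression universe to a
    significance boolean; ``gene_set`` must be a subset of the universe.
    Each of ``n_boot`` replicates samples ``sample_size`` genes (without
    replacement by default) and records the percentage significant; the
    result's percentile is 100 * (# replicates strictly below the observed
    percentage) / n_boot, labelled ">99.9" when the observed value exceeds
    every replicate.  Replicate ties with the observed value count as
    not-below, a conservative choice.  Fully reproducible for a fixed seed.
    """
    sig = pd.Series(gene_significance).astype(bool)
    universe = sig.index
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(universe)
    if missing:
        raise ValueError(f"gene set not a subset of the universe: {sorted(missing)[:5]}")
    if sample_size > len(universe):
        raise ValueError("sample_size exceeds universe size")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    observed = 100.0 * sig.loc[gene_set].mean()
    flags = sig.to_numpy()
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.choice(flags.size, size=sample_size, replace=with_replacement)
        reps[i] = flags[idx].mean()
    reps *= 100.0
    n_below = int((reps < observed).sum())
    percentile = 100.0 * n_below / n_boot
    label = ">99.9" if n_below == n_boot else f"{percentile:.1f}"
    return BootstrapResult(
        observed_percent=float(observed),
        n_boot=n_boot,
        sample_size=sample_size,
        bootstrap_mean=float(reps.mean()),
        ci95_halfwidth=float(1.959963984540054 * reps.std(ddof=1)) if n_boot > 1 else 0.0,
        percentile=percentile,
        percentile_label=label,
        seed=seed,
    )


def set_vs_genome_enrichment(
    calls: pd.DataFrame,
    gene_set: Iterable[str],
    flag_column: str = "significant",
    disjoint: bool = False,
) -> dict:
    """Build the set-vs-genome 2x2 table and run both tests.

    ``calls`` carries one row per gene with data (gene_id plus a boolean
    ``flag_column``); genes absent from it are treated as having no data and
    are dropped from both the set and the genome counts.  By default the
    genome rows include the gene set (set significant / set total vs genome
    significant / genome total), matching the construction whose statistic
    the pipeline reports; ``disjoint=True`` subtracts the set from the
    genome rows instead.
    """
    flags = calls.set_index("gene_id")[flag_column].astype(bool)
    set_ids = [g for g in gene_set if g in flags.index]
    if not set_ids:
        raise ValueError("gene set does not intersect the calls table")
    a = int(flags.loc[set_ids].sum())
    b = len(set_ids) - a
    if disjoint:
        genome = flags.drop(index=set_ids)
    else:
        genome = flags
    c = int(genome.sum())
    d = int(len(genome) - c)
    table = ContingencyTable2x2(a, b, c, d)
    stat, df, p = yates_chi_square(table)
    orr, ci = odds_ratio(table)
    return {
        "table": table,
        "chi_square": stat,
        "df": df,
        "p_value": p,
        "odds_ratio": orr,
        "or_ci95": ci,
        "n_set": len(set_ids),
        "n_genome": len(genome),
    }


def read_gene_set(path: str | Path) -> list[str]:
    """Read a gene-set list: one gene id per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
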