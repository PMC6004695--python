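"""End-to-end orchestration: filter -> per-gene stats -> selection calls ->
outlier classification -> enrichment -> concordance.

A single YAML config names every input artifact and parameter; each stage
writes its TSV into the output directory, and a JSON summary plus a
MANIFEST (inputs, parameters, seed, completed stages) make runs auditable.
Stage failures raise :class:`StageError` with the stage name; outputs of
completed stages are kept and the MANIFEST records how far the run got.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment_stats import (
    bootstrap_expression_enrichment,
    read_gene_set,
    set_vs_genome_enrichment,
)
from .expression_concordance import (
    call_directions,
    concordance,
    orthogroup_summary,
    read_de_table,
    read_ortholog_map,
)
from .outlier_ranking import OutlierThresholds, classify_outliers, write_outlier_calls
from .popgen_stats import (
    GeneAnnotation,
    compute_per_gene_stats,
    filter_sites,
    read_bed,
    read_vcf,
    write_per_gene_stats,
)
from .selection_scan import (
    fit_normal_pvalues,
    gene_selection_calls,
    read_selection_stats,
    write_selection_calls,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

logger = logging.getLogger("cavescan")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    vcf: str
    genes_bed: str
    selection_stats: str
    fish_de: str
    human_de: str
    ortholog_map: str
    gene_set: str
    output_dir: str
    seed: int = 0
    masks_bed: str | None = None
    indels_bed: str | None = None
    selection_gene_set: str | None = None
    pop1_prefix: str = "surface"
    pop2_prefix: str = "cave"
    min_individuals: int = 6
    fst_method: str = "weighted"
    thresholds: OutlierThresholds = field(default_factory=OutlierThresholds)
    alpha: float = 0.05
    n_boot: int = 9999
    sample_size: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr is not None:
            cfg.thresholds = OutlierThresholds(**thr)
        return cfg

    def check_paths(self) -> None:
        for name in ("vcf", "genes_bed", "selection_stats", "fish_de",
                     "human_de", "ortholog_map", "gene_set",
                     "masks_bed", "indels_bed", "selection_gene_set"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file: {p}")


def _load_annotation(config: PipelineConfig) -> GeneAnnotation:
    genes = read_bed(config.genes_bed, with_name=True)
    masks = read_bed(config.masks_bed) if config.masks_bed else None
    indels = read_bed(config.indels_bed) if config.indels_bed else None
    kwargs = {}
    if masks is not None:
        kwargs["masks"] = masks
    if indels is not None:
        kwargs["indels"] = indels
    return GeneAnnotation(genes=genes, **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the summary report (also written as JSON)."""
    config.check_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"seed": config.seed, "version": __version__}

    def manifest() -> None:
        rec = {
            "version": __version__,
            "seed": config.seed,
            "completed_stages": completed,
            "parameters": {
                "min_individuals": config.min_individuals,
                "fst_method": config.fst_method,
                "thresholds": asdict(config.thresholds),
                "alpha": config.alpha,
                "n_boot": config.n_boot,
                "sample_size": config.sample_size,
            },
            "inputs": {k: getattr(config, k) for k in (
                "vcf", "genes_bed", "masks_bed", "indels_bed",
                "selection_stats", "fish_de", "human_de",
                "ortholog_map", "gene_set")},
        }
        (out / "MANIFEST.json").write_text(json.dumps(rec, indent=2) + "\n")

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                fn()
                completed.append(name)
                manifest()
                logger.info("stage %s: done", name)
            except Exception as exc:  # noqa: BLE001 - stage-tag and re-raise
                manifest()
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("popgen")
    def _popgen() -> None:
        annotation = _load_annotation(config)
        from cyvcf2 import VCF

        samples = list(VCF(config.vcf).samples)
        pop1 = [s for s in samples if s.startswith(config.pop1_prefix)]
        pop2 = [s for s in samples if s.startswith(config.pop2_prefix)]
        if not pop1 or not pop2:
            raise ValueError(
                f"sample prefixes {config.pop1_prefix!r}/{config.pop2_prefix!r} "
                "match no VCF samples")
        dataset = read_vcf(config.vcf, pop1, pop2)
        filtered, flog = filter_sites(dataset, annotation, config.min_individuals)
        stats = compute_per_gene_stats(filtered, annotation, config.fst_method)
        write_per_gene_stats(stats, out / "per_gene_stats.tsv")
        state["annotation"] = annotation
        state["stats"] = stats
        summary["site_filter"] = flog.as_dict()

    @stage("scan")
    def _scan() -> None:
        raw = read_selection_stats(config.selection_stats)
        pvals = fit_normal_pvalues(raw)
        calls = gene_selection_calls(pvals, state["annotation"], config.alpha)
        write_selection_calls(calls, out / "selection_calls.tsv")
        state["selection_calls"] = calls
        summary["selection"] = {
            "n_genes_with_data": len(calls),
            "n_significant": int(calls["significant"].sum()),
        }

    @stage("rank")
    def _rank() -> None:
        calls = classify_outliers(state["stats"], state["selection_calls"],
                                  config.thresholds)
        write_outlier_calls(calls, out / "outlier_calls.tsv")
        state["outliers"] = calls
        summary["outliers"] = {
            "n_genes": len(calls),
            "n_outliers": int(calls["is_outlier"].sum()),
            "n_fst_outliers": int(calls["fst_outlier"].sum()),
            "n_dxy_outliers": int(calls["dxy_outlier"].sum()),
            "n_hapflk_significant": int(calls["hapflk_significant"].sum()),
            "n_pi_excluded": int(calls["pi_excluded"].sum()),
        }

    @stage("enrich")
    def _enrich() -> None:
        gene_set = read_gene_set(config.gene_set)
        sel = state["selection_calls"]
        if config.selection_gene_set:
            sel_set = read_gene_set(config.selection_gene_set)
        else:
            sel_set = _fish_set(gene_set, config)
        enr = set_vs_genome_enrichment(sel, sel_set, "significant")
        human_de = read_de_table(config.human_de)
        sig = pd.Series(
            (human_de["padj"] < config.alpha).to_numpy(),
            index=human_de["gene_id"])
        boot = bootstrap_expression_enrichment(
            sig, [g for g in gene_set if g in sig.index],
            n_boot=config.n_boot, sample_size=config.sample_size,
            seed=config.seed)
        t = enr["table"]
        summary["enrichment"] = {
            "contingency": [t.a, t.b, t.c, t.d],
            "chi_square": enr["chi_square"],
            "df": enr["df"],
            "p_value": enr["p_value"],
            "odds_ratio": enr["odds_ratio"],
            "or_ci95": list(enr["or_ci95"]),
            "bootstrap": {
                "observed_percent": boot.observed_percent,
                "mean": boot.bootstrap_mean,
                "ci95_halfwidth": boot.ci95_halfwidth,
                "percentile": boot.percentile_label,
                "n_boot": boot.n_boot,
                "sample_size": boot.sample_size,
                "seed": boot.seed,
            },
        }

    @stage("concord")
    def _concord() -> None:
        omap = read_ortholog_map(config.ortholog_map)
        fish_dir = call_directions(read_de_table(config.fish_de), config.alpha)
        human_dir = call_directions(read_de_table(config.human_de), config.alpha)
        og = orthogroup_summary(fish_dir, omap)
        res = concordance(fish_dir, human_dir, omap)
        og["per_orthogroup"].to_csv(out / "orthogroup_summary.tsv", sep="\t", index=False)
        res.per_gene.to_csv(out / "concordance_per_gene.tsv", sep="\t", index=False)
        summary["concordance"] = {
            "n_jointly_de": res.n_jointly_de,
            "n_same_direction": res.n_same_direction,
            "percent_same_direction": res.percent_same_direction,
            "n_excluded_inconsistent": res.n_excluded_inconsistent,
            "orthogroup_percent_significant": og["orthogroup_percent_significant"],
            "paralog_percent_significant": og["paralog_percent_significant"],
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _fish_set(gene_set: list[str], config: PipelineConfig) -> list[str]:
    """Resolve a human gene set to fish paralog ids via the ortholog map;
    ids already present on the fish side pass through unchanged."""
    omap = read_ortholog_map(config.ortholog_map)
    by_human = omap.groupby("human_gene")["fish_paralog"].apply(list)
    out: list[str] = []
    for g in gene_set:
        out.extend(by_human.get(g, [g]))
    return sorted(set(out))
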