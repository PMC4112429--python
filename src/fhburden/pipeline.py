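"""End-to-end discovery cascade.

Stage order, mirroring the study design:

1. Tier-1 screen: cases carrying a catalogued FH mutation in an
   established gene are explained and removed.
2. Polygenic triage: remaining cases with a complete LDL-C gene score
   strictly above the top-decile cutoff are explained as polygenic and
   removed.  A sample that is both mutation-positive and high-score counts
   once, under the Tier-1 heading.  Unscorable samples are never excluded
   on score grounds.
3. Whole-exome burden scan over the remaining cases versus all controls,
   on novel functional carrier events.

The report carries the exclusion arithmetic
(``n_remaining = n_total - n_tier1 - n_polygenic``), the per-sample triage
table, the sorted burden results and a per-stage run log; identical inputs
produce identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import burden as burden_mod
from . import filtering
from .burden import GeneBurdenResult, round_sig, run_burden_scan
from .genescore import (
    DEFAULT_CUTOFF,
    GeneScoreResult,
    SnpWeight,
    load_genotypes,
    load_weights,
    score_cohort,
)
from .tier1 import KnownMutation, SampleTriage, explained_samples, load_catalogue, screen_tier1
from .variant_model import CohortDataset, read_cohort

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "run_pipeline_data",
    "burden_table",
    "write_report",
]


@dataclass
class PipelineParams:
    """Thresholds of the cascade; defaults are the study settings."""

    variant_class: str = "novel"  # "novel" (exome scan) | "rare" (candidate lists)
    rare_threshold: float = filtering.RARE_THRESHOLD
    score_cutoff: float = DEFAULT_CUTOFF
    max_control_variants: int = burden_mod.MAX_CONTROL_VARIANTS
    p_flag_threshold: float = burden_mod.P_FLAG_THRESHOLD
    exclude_chroms: tuple[str, ...] = tuple(sorted(burden_mod.DEFAULT_EXCLUDED_CHROMS))

    def predicate(self):
        if self.variant_class == "novel":
            return lambda v: filtering.novel_functional(v, self.rare_threshold)
        if self.variant_class == "rare":
            return lambda v: filtering.rare_functional(v, self.rare_threshold)
        raise ValueError(f"variant_class must be 'novel' or 'rare', got {self.variant_class!r}")


@dataclass
class PipelineConfig:
    """File-based run configuration (YAML)."""

    case_vcfs: list[str]
    control_vcfs: list[str]
    annotation: str
    catalogue: str
    weights: str
    genotypes: str
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        base = Path(path).parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        return cls(
            case_vcfs=[resolve(p) for p in raw.pop("case_vcfs")],
            control_vcfs=[resolve(p) for p in raw.pop("control_vcfs")],
            annotation=resolve(raw.pop("annotation")),
            catalogue=resolve(raw.pop("catalogue")),
            weights=resolve(raw.pop("weights")),
            genotypes=resolve(raw.pop("genotypes")),
            params=params,
        )


@dataclass
class PipelineReport:
    n_total_cases: int
    n_tier1_excluded: int
    n_polygenic_excluded: int
    n_remaining: int
    triage: dict[str, SampleTriage]
    burden_results: list[GeneBurdenResult]
    scores: dict[str, GeneScoreResult]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_remaining != self.n_total_cases - self.n_tier1_excluded - self.n_polygenic_excluded:
            raise AssertionError("exclusion arithmetic violated")


def run_pipeline_data(
    dataset: CohortDataset,
    catalogue: Sequence[KnownMutation],
    genotypes_by_sample: Mapping[str, Mapping[str, tuple[str, str]]],
    weights: Sequence[SnpWeight],
    params: PipelineParams | None = None,
) -> PipelineReport:
    """Run the cascade on in-memory objects."""
    params = params or PipelineParams()
    log: list[str] = []
    n_total = dataset.case_n
    log.append(f"cohort: {n_total} cases, {dataset.control_n} controls, {len(dataset.calls)} calls")

    # stage 1: tier-1 screen ------------------------------------------------
    try:
        matches = screen_tier1(dataset, list(catalogue))
        tier1_set = explained_samples(matches)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage tier1 failed: {exc}") from exc
    log.append(f"tier1: {len(tier1_set)} cases explained by a catalogued mutation")

    # stage 2: gene-score triage -------------------------------------------
    try:
        case_genotypes = {s: genotypes_by_sample.get(s, {}) for s in dataset.cases}
        scores = score_cohort(case_genotypes, list(weights), cutoff=params.score_cutoff)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage genescore failed: {exc}") from exc
    high_score = {s for s, r in scores.items() if r.classification == "polygenic"}
    unscored = sorted(s for s, r in scores.items() if r.classification == "unscored")
    polygenic_set = high_score - tier1_set  # tier1 takes precedence
    log.append(
        f"genescore: {len(high_score)} cases above cutoff {params.score_cutoff} "
        f"({len(high_score & tier1_set)} also tier1-matched, counted under tier1); "
        f"{len(unscored)} unscorable, retained"
    )

    # stage 3: exclusion ----------------------------------------------------
    triage: dict[str, SampleTriage] = {}
    for sample in sorted(dataset.cases):
        if sample in tier1_set:
            evidence = "; ".join(
                f"{m.mutation.gene}:{m.mutation.hgvs_c or m.mutation.key}" for m in matches.get(sample, [])
            )
            triage[sample] = SampleTriage(sample, "tier1_mutation", evidence)
        elif sample in polygenic_set:
            triage[sample] = SampleTriage(sample, "polygenic", f"score={scores[sample].total:.3f}")
        else:
            triage[sample] = SampleTriage(sample, "unexplained")
        if sample in matches and sample not in tier1_set:
            # reported-only hits (recessive het, unknown-effect variants)
            hits = "; ".join(f"{m.mutation.gene}:{m.mutation.hgvs_c or m.mutation.key}" for m in matches[sample])
            log.append(f"sample {sample}: non-explaining tier1 hit(s) {hits}; retained")
    remaining = sorted(dataset.cases - tier1_set - polygenic_set)
    log.append(
        f"exclusion: {n_total} - {len(tier1_set)} tier1 - {len(polygenic_set)} polygenic "
        f"= {len(remaining)} cases remain"
    )

    # stage 4-5: filtering + burden scan ------------------------------------
    try:
        subset = dataset.subset_cases(remaining)
        counts = filtering.collect_gene_counts(subset, params.predicate())
        results = run_burden_scan(
            counts,
            n_case=subset.case_n,
            n_control=subset.control_n,
            max_control_variants=params.max_control_variants,
            p_flag_threshold=params.p_flag_threshold,
            exclude_chroms=params.exclude_chroms,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage burden failed: {exc}") from exc
    n_flagged = sum(r.flagged for r in results)
    n_tested = sum(r.status == "tested" for r in results)
    log.append(
        f"burden: {len(counts)} genes with qualifying events, {n_tested} tested, "
        f"{n_flagged} flagged at p < {params.p_flag_threshold}"
    )

    return PipelineReport(
        n_total_cases=n_total,
        n_tier1_excluded=len(tier1_set),
        n_polygenic_excluded=len(polygenic_set),
        n_remaining=len(remaining),
        triage=triage,
        burden_results=results,
        scores=scores,
        log=log,
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """File-based entry point: read all inputs, then run the cascade."""
    try:
        dataset = read_cohort(config.case_vcfs, config.control_vcfs, config.annotation)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage ingest failed: {exc}") from exc
    catalogue = load_catalogue(config.catalogue)
    weights = load_weights(config.weights)
    genotypes = load_genotypes(config.genotypes)
    report = run_pipeline_data(dataset, catalogue, genotypes, weights, config.params)
    report.log = dataset.log + report.log
    return report


def burden_table(results: Sequence[GeneBurdenResult]) -> pd.DataFrame:
    """Tabulate burden results, one row per gene, sorted as reported."""

    def variant_label(v) -> str:
        return v.hgvs_c or f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "k_case": r.k_case,
                "k_control": r.k_control,
                "p_value": r.p_value,
                "p_2sf": round_sig(r.p_value, 2) if r.p_value is not None else None,
                "p_bonferroni": r.p_bonferroni,
                "status": r.status,
                "flagged": r.flagged,
                "case_variants": "; ".join(variant_label(v) for v in r.case_variants),
                "control_variants": "; ".join(variant_label(v) for v in r.control_variants),
            }
            for r in results
        ]
    )


def write_report(report: PipelineReport, outdir: str | Path) -> dict[str, Path]:
    """Write the burden table, triage table and run log as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "burden": outdir / "burden_results.tsv",
        "triage": outdir / "triage.tsv",
        "log": outdir / "run_log.txt",
        "summary": outdir / "summary.tsv",
    }
    burden_table(report.burden_results).to_csv(paths["burden"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample_id": t.sample_id, "status": t.status, "evidence": t.evidence}
            for t in (report.triage[s] for s in sorted(report.triage))
        ]
    ).to_csv(paths["triage"], sep="\t", index=False)
    paths["log"].write_text("\n".join(report.log) + "\n")
    pd.DataFrame(
        [
            {
                "n_total_cases": report.n_total_cases,
                "n_tier1_excluded": report.n_tier1_excluded,
                "n_polygenic_excluded": report.n_polygenic_excluded,
                "n_remaining": report.n_remaining,
            }
        ]
    ).to_csv(paths["summary"], sep="\t", index=False)
    return paths
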